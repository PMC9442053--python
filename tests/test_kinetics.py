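"""Rate laws, ODE right-hand side, integration, observables, chemostat."""

import numpy as np
import pytest

from drumalg import (
    CultureState,
    ForcingProtocol,
    KineticParameterSet,
    build_variant,
    kinetic_rates,
    observables,
    ode_rhs,
    reference_parameters,
    run_chemostat_to_steady_state,
    simulate,
)
from drumalg.chemostat import excreted_fraction
from drumalg.forcing import PiecewiseConstant, day_night_light
from drumalg.simulate import DegenerateStateError, Trajectory

REPLETE_STATE = CultureState(
    S=5.7e-4, GAP=2.4e-5, G6P=1.1e-5, PEP=3.5e-4, PA=1.8e-4, CARB=3.2e-3,
    B=1.1e-3, P=0.0,
)


def constant_forcing(d_per_day=0.0, s_in=0.0, light=0.0):
    return ForcingProtocol.chemostat(d_per_day, s_in, light)


def zero_params(with_ex=True):
    kw = dict(k_MR1=0, k_MR2=0, k_MR2p=0, k_MR3=0, k_MR3p=0,
              k_MR4=0, k_MR4p=0, k_MR5=0, k_MR5p=0, k_MR6=0)
    if with_ex:
        kw["k_EX"] = 0
    return KineticParameterSet(**kw)


class TestKineticRates:
    def test_night_shuts_down_photosynthesis(self, excarb, excarb_params):
        alpha = kinetic_rates(excarb, REPLETE_STATE, excarb_params, light=0.0)
        assert alpha[0] == 0.0

    def test_mass_action_ratio_arithmetic(self, excarb, excarb_params):
        # GAP/B = 0.1 with k_MR2 = 6.07 gives alpha_MR2 = 0.607 per hour
        state = CultureState(S=1e-4, GAP=1e-4, G6P=0, PEP=0, PA=0, CARB=0, B=1e-3, P=0)
        alpha = kinetic_rates(excarb, state, excarb_params, light=100.0)
        assert alpha[1] == pytest.approx(0.607)
        assert alpha[0] == pytest.approx(excarb_params.k_MR1 * 100.0)

    def test_no_biomass_synthesis_without_nitrate(self, excarb, excarb_params):
        starved = CultureState(S=0.0, GAP=1e-5, G6P=1e-5, PEP=1e-4, PA=1e-4,
                               CARB=1e-3, B=1e-3, P=0.0)
        alpha = kinetic_rates(excarb, starved, excarb_params, light=500.0)
        assert alpha[6] == 0.0

    def test_degenerate_biomass_rejected(self, excarb, excarb_params):
        state = CultureState(S=1e-4, B=0.0)
        with pytest.raises(DegenerateStateError):
            kinetic_rates(excarb, state, excarb_params, light=100.0)

    def test_reversible_rates_signed(self, excarb, excarb_params):
        # huge PA pool drives net lipid synthesis backwards
        state = CultureState(S=1e-4, GAP=1e-9, G6P=1e-5, PEP=1e-9, PA=1e-2,
                             CARB=1e-3, B=1e-3, P=0.0)
        alpha = kinetic_rates(excarb, state, excarb_params, light=0.0)
        assert alpha[5] < 0


class TestOdeRhs:
    def test_pure_washout_with_zero_kinetics(self, excarb):
        params = zero_params()
        d_h = 0.3 / 24.0
        forcing = constant_forcing(0.3, s_in=2e-3, light=100.0)
        x = REPLETE_STATE.as_array()
        dx = ode_rhs(0.0, REPLETE_STATE, excarb, params, forcing)
        expected = -d_h * x
        expected[0] += d_h * 2e-3
        np.testing.assert_allclose(dx, expected, rtol=1e-12)

    def test_dark_starved_carbon_leaves_only_as_co2(self, woex):
        params = reference_parameters("w/oEx")
        forcing = constant_forcing(0.0, 0.0, 0.0)
        state = CultureState(S=0.0, GAP=1e-5, G6P=1e-5, PEP=1e-4, PA=1e-4,
                             CARB=1e-3, B=1e-3, P=0.0)
        dx = ode_rhs(0.0, state, woex, params, forcing)
        alpha = kinetic_rates(woex, state, params, light=0.0)
        c = woex.dynamic_atoms("C")
        dxc = float(c @ dx)
        assert alpha[6] == 0.0  # no nitrate, no biomass synthesis
        assert dxc == pytest.approx(-16.61 * alpha[5] * state.B, rel=1e-10)

    def test_carb_accumulates_by_day_and_is_reused_at_starved_night(
        self, excarb, excarb_params, day_night_protocol, initial_state
    ):
        traj = simulate(excarb, excarb_params, day_night_protocol, initial_state,
                        (-120.0, 96.0), t_eval=np.array([78.0, 90.0]),
                        rtol=1e-8, atol=1e-12)
        i_carb = 5
        day_dx = ode_rhs(78.0, traj.states[0], excarb, excarb_params, day_night_protocol)
        night_dx = ode_rhs(90.0, traj.states[1], excarb, excarb_params, day_night_protocol)
        assert day_dx[i_carb] > 0
        assert night_dx[i_carb] < 0


class TestSimulate:
    def test_zero_kinetics_closed_form(self, excarb):
        params = zero_params()
        d_per_day, s_in = 0.6, 1.5e-3
        forcing = constant_forcing(d_per_day, s_in, light=0.0)
        t_eval = np.linspace(0.0, 96.0, 9)
        traj = simulate(excarb, params, forcing, REPLETE_STATE, (0.0, 96.0),
                        t_eval=t_eval, rtol=1e-10, atol=1e-14)
        d_h = d_per_day / 24.0
        decay = np.exp(-d_h * t_eval)
        x0 = REPLETE_STATE.as_array()
        np.testing.assert_allclose(
            traj.states[:, 0], s_in + (x0[0] - s_in) * decay, rtol=1e-7)
        for i in range(1, 8):
            np.testing.assert_allclose(traj.states[:, i], x0[i] * decay,
                                       rtol=1e-7, atol=1e-20)

    def test_zero_excretion_reproduces_no_excretion_variant(
        self, excarb, woex, day_night_protocol, initial_state
    ):
        params_off = reference_parameters("w/oEx*")
        params_ex = params_off.updated(k_EX=0.0)
        t_eval = np.arange(-48.0, 48.1, 4.0)
        kw = dict(t_eval=t_eval, rtol=1e-8, atol=1e-12)
        a = simulate(excarb, params_ex, day_night_protocol, initial_state, (-48.0, 48.0), **kw)
        b = simulate(woex, params_off, day_night_protocol, initial_state, (-48.0, 48.0), **kw)
        # the extra all-zero MR7 column changes floating-point summation order,
        # so agreement is to solver tolerance rather than bitwise
        np.testing.assert_allclose(a.states, b.states, rtol=1e-6, atol=1e-15)
        assert np.all(a.states[:, 7] == 0.0)  # nothing excreted with k_EX = 0

    def test_replete_periodic_regime_after_warmup(self, excarb, excarb_params, initial_state):
        forcing = ForcingProtocol(
            light=day_night_light(1500.0),
            dilution=PiecewiseConstant.constant(0.25 / 24.0),
            inflow_substrate=PiecewiseConstant.constant(2e-3),
            light_breaks_per_day=(0.0, 12.0),
        )
        traj = simulate(excarb, excarb_params, forcing, initial_state,
                        (0.0, 960.0), t_eval=np.array([936.0, 960.0]),
                        rtol=1e-9, atol=1e-13)
        x1, x2 = traj.states
        assert np.max(np.abs(x2 - x1) / np.maximum(np.abs(x2), 1e-15)) < 1e-3

    def test_pulse_is_instantaneous_jump(self, excarb, excarb_params,
                                         day_night_protocol, initial_state):
        t_pulse = 132.0
        traj = simulate(excarb, excarb_params, day_night_protocol, initial_state,
                        (-120.0, 140.0), t_eval=np.array([t_pulse, t_pulse + 0.05]),
                        rtol=1e-8, atol=1e-12)
        s_before, s_after = traj.states[:, 0]
        assert s_after - s_before > 0.9 * 2.7e-3 / 14.0

    def test_t_eval_outside_span_rejected(self, excarb, excarb_params, day_night_protocol):
        with pytest.raises(ValueError):
            simulate(excarb, excarb_params, day_night_protocol, REPLETE_STATE,
                     (0.0, 10.0), t_eval=np.array([20.0]))


class TestObservables:
    def test_pure_functional_biomass_ratios(self, excarb, excarb_params):
        state = CultureState(S=0.0, B=1e-3)
        traj = Trajectory(times=np.array([0.0]), states=state.as_array()[None, :],
                          network=excarb, params=excarb_params,
                          forcing=constant_forcing())
        obs = observables(traj).iloc[0]
        c_b = excarb.species_by_name("B").carbon_atoms
        assert obs["XC_molC_per_L"] == pytest.approx(c_b * 1e-3)
        assert obs["carb_quota"] == 0 and obs["lipid_quota"] == 0
        assert obs["NC_quota_gN_per_gC"] == pytest.approx(
            1.31 * 14.007 / (8.5442 * 12.011), rel=1e-6)
        assert obs["NC_quota_gN_per_gC"] == pytest.approx(0.179, abs=2e-3)

    def test_quota_homogeneity_under_scaling(self, excarb, excarb_params):
        x = REPLETE_STATE.as_array()
        forcing = constant_forcing(light=200.0)
        quota_cols = ["carb_quota", "lipid_quota", "NC_quota_gN_per_gC"]
        obs1 = observables(Trajectory(np.array([0.0]), x[None, :], excarb,
                                      excarb_params, forcing)).iloc[0]
        obs2 = observables(Trajectory(np.array([0.0]), 2 * x[None, :], excarb,
                                      excarb_params, forcing)).iloc[0]
        for col in quota_cols:
            assert obs2[col] == pytest.approx(obs1[col], rel=1e-12)
        assert obs2["XC_molC_per_L"] == pytest.approx(2 * obs1["XC_molC_per_L"])

    def test_adding_carbohydrate_raises_xc_lowers_nc(self, excarb, excarb_params):
        forcing = constant_forcing(light=200.0)
        x = REPLETE_STATE.as_array()
        x_more = x.copy()
        x_more[5] *= 2  # CARB
        obs1 = observables(Trajectory(np.array([0.0]), x[None, :], excarb,
                                      excarb_params, forcing)).iloc[0]
        obs2 = observables(Trajectory(np.array([0.0]), x_more[None, :], excarb,
                                      excarb_params, forcing)).iloc[0]
        assert obs2["XC_molC_per_L"] > obs1["XC_molC_per_L"]
        assert obs2["NC_quota_gN_per_gC"] < obs1["NC_quota_gN_per_gC"]


class TestConservation:
    def test_nitrogen_changes_only_through_dilution_and_pulses(
        self, excarb, excarb_params, day_night_protocol, initial_state
    ):
        traj = simulate(excarb, excarb_params, day_night_protocol, initial_state,
                        (-120.0, 168.0), t_eval=np.arange(-120.0, 168.1, 6.0),
                        rtol=1e-9, atol=1e-13, audit=True)
        c_resid, n_resid = traj.conservation_residuals()
        assert n_resid < 1e-7
        assert c_resid < 1e-7


class TestChemostat:
    def test_washout_flagged_not_raised(self, excarb, excarb_params):
        res = run_chemostat_to_steady_state(excarb, excarb_params, 5.0,
                                            s_in=5e-2, n_restarts=0)
        assert res.washout
        assert res.state.B < 1e-9

    def test_invalid_dilution_rejected(self, excarb, excarb_params):
        with pytest.raises(ValueError):
            run_chemostat_to_steady_state(excarb, excarb_params, -0.1)

    def test_excreted_fraction_zero_cases(self, excarb, woex, excarb_params):
        alpha = np.zeros(8)
        alpha[0] = 1.0
        assert excreted_fraction(excarb, alpha) == 0.0
        assert excreted_fraction(woex, np.zeros(7)) == 0.0

    def test_excreted_fraction_is_a_flux_ratio(self, excarb, excarb_params):
        # invariant to rescaling all concentrations at fixed quotas: alpha is
        # ratio-based, so recomputing rates at a scaled state gives equal rates
        x = REPLETE_STATE.as_array()
        a1 = kinetic_rates(excarb, x, excarb_params, light=300.0)
        a2 = kinetic_rates(excarb, 3.0 * x, excarb_params, light=300.0)
        # every rate entering the fraction is ratio- or light-based (only the
        # nitrate-dependent biomass synthesis rate scales with concentration)
        np.testing.assert_allclose(np.delete(a1, 6), np.delete(a2, 6), rtol=1e-12)
        assert excreted_fraction(excarb, a1) == pytest.approx(
            excreted_fraction(excarb, a2))
        assert excreted_fraction(excarb, a1) == pytest.approx(
            100.0 * 6.0 * a1[7] / (3.0 * a1[0]))
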