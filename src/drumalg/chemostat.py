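"""Chemostat steady states of the macro-reaction model.

A nitrogen-limited chemostat at dilution rate D (1/d) under constant light has
a useful structure: the intracellular pool ratios a = A/B evolve independently
of the biomass scale (dilution cancels in the ratios), so the equilibrium is
found by (i) settling the ratio subsystem at fixed extracellular nitrate S,
(ii) root-finding the residual nitrate S* at which the specific biomass
synthesis rate equals D — if even S* = S_in cannot sustain D the culture
washes out — and (iii) reconstructing the full state, confirming stationarity
by integration (relative change over a 24 h window below tolerance) and
polishing with a Newton solve.  At a non-washout equilibrium the specific net
production rate of particulate carbon equals D, the defining fixed-point
property of the chemostat; the steady-state quotas are independent of the
inflow concentration S_in, which only sets the biomass scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .forcing import HOURS_PER_DAY, ForcingProtocol
from .network import DYNAMIC_SPECIES, MW_C, MW_N, MacroReactionNetwork
from .params import KineticParameterSet
from .simulate import CultureState, _Compiled, simulate

__all__ = [
    "SteadyStateResult",
    "run_chemostat_to_steady_state",
    "max_growth_rate",
    "sweep_dilution",
    "excreted_fraction",
    "quota_rate_table",
]

#: biomass floor below which a run is declared washed out (mol B / L)
WASHOUT_FLOOR = 1e-9

_IDX = {name: i for i, name in enumerate(DYNAMIC_SPECIES)}
_I_S, _I_B = _IDX["NO3"], _IDX["B"]
_PART = [i for i, sp in enumerate(DYNAMIC_SPECIES) if sp not in ("NO3", "P")]



@dataclass
class SteadyStateResult:
    """Equilibrium of one chemostat run."""

    dilution_per_day: float
    state: CultureState
    growth_rate_per_day: float
    nitrogen_quota: float  # X_N:X_C, gN/gC
    carb_quota: float  # carbohydrate carbon fraction of X_C
    lipid_quota: float  # neutral-lipid carbon fraction of X_C
    excreted_fraction_pct: float
    excretion_rate_per_day: float  # excreted C per particulate C per day
    washout: bool
    converged: bool
    initial_condition_spread: float | None = None  # max rel. disagreement across restarts

    @property
    def equilibria_agree(self) -> bool:
        return self.initial_condition_spread is None or self.initial_condition_spread < 1e-3


def _equilibrium_summary(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    x: np.ndarray,
    d_per_day: float,
    s_in: float,
    light: float,
    converged: bool,
    net_fixation_basis: bool = False,
) -> SteadyStateResult:
    compiled = _Compiled(network, params)
    cC = compiled.cC
    cN = compiled.cN
    xc = float(x[_PART] @ cC[_PART])
    xn = float(x[_PART] @ cN[_PART])
    d_h = d_per_day / HOURS_PER_DAY
    dx = compiled.rhs(0.0, x, light, d_h, s_in)
    dxc = float(dx[_PART] @ cC[_PART])
    mu_h = (dxc + d_h * xc) / xc if xc > 0 else 0.0
    alpha = compiled.rates(x, light)
    carb_c = network.species_by_name("CARB").carbon_atoms * x[_IDX["CARB"]]
    pa_c = network.species_by_name("PA").carbon_atoms * x[_IDX["PA"]]
    frac = excreted_fraction(network, alpha, net_fixation_basis=net_fixation_basis)
    if network.variant.excretion_locus is not None:
        c_p = network.species_by_name("P").carbon_atoms
        j_ex = network.reaction_ids.index("MR7")
        eta_h = c_p * alpha[j_ex] * x[_IDX["B"]] / xc if xc > 0 else 0.0
    else:
        eta_h = 0.0
    return SteadyStateResult(
        dilution_per_day=d_per_day,
        state=CultureState.from_array(x),
        growth_rate_per_day=mu_h * HOURS_PER_DAY,
        nitrogen_quota=(xn * MW_N) / (xc * MW_C) if xc > 0 else float("nan"),
        carb_quota=carb_c / xc if xc > 0 else float("nan"),
        lipid_quota=pa_c / xc if xc > 0 else float("nan"),
        excreted_fraction_pct=frac,
        excretion_rate_per_day=eta_h * HOURS_PER_DAY,
        washout=x[_IDX["B"]] < WASHOUT_FLOOR,
        converged=converged,
    )


def _integrate_to_stationary(
    network, params, forcing, initial, tol, max_days, rtol, atol
):
    """Integrate under constant forcing until the 24 h relative change < tol."""
    x = initial.as_array()
    t = 0.0
    chunk = 10 * HOURS_PER_DAY
    scale = None
    for _ in range(int(max_days // 10) + 1):
        traj = simulate(
            network, params, forcing, CultureState.from_array(x),
            (t, t + chunk), t_eval=np.arange(t, t + chunk + 1e-9, HOURS_PER_DAY),
            rtol=rtol, atol=atol,
        )
        states = traj.states
        x = states[-1]
        if x[_IDX["B"]] < WASHOUT_FLOOR:
            return x, True, True  # washout is an absorbing, converged outcome
        scale = np.maximum(np.max(np.abs(states), axis=0), 1e-14)
        rel = np.abs(states[-1] - states[-2]) / scale
        if float(np.max(rel)) < tol:
            return x, True, False
        t += chunk
    return x, False, False


_POOL_ROWS = [_IDX[s] for s in ("GAP", "G6P", "PEP", "PA", "CARB")]
_J_MR6 = 6  # MR6 column index (reaction ordering is fixed by construction)

_DEFAULT_RATIOS = np.array([1e-2, 1e-2, 1e-2, 1e-1, 1e-1])


def _settle_ratios(
    compiled, s: float, light: float, u0: np.ndarray | None = None,
    tol: float = 1e-9, max_days: float = 20000.0, newton_first: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium pool ratios a = A/B at fixed nitrate S and light.

    Dilution cancels in the ratios, so the subsystem
    da/dt = (K' alpha)_A - a alpha_MR6 is autonomous.  With ``newton_first``
    and a warm start ``u0`` (continuation along a nitrate sweep) the
    equilibrium is solved directly by Newton; otherwise, or when Newton leaves
    the positive orthant, the subsystem is integrated in chunks until
    stationary and then polished.  Returns (a*, alpha(a*, S)).
    """
    K_pools = compiled.K[_POOL_ROWS, :]

    def rhs(t, u):
        x = np.zeros(8)
        x[_I_S] = s
        x[_POOL_ROWS] = u
        x[_I_B] = 1.0
        alpha = compiled.rates(x, light)
        return K_pools @ alpha - u * alpha[_J_MR6]

    def finish(u):
        x = np.zeros(8)
        x[_I_S] = s
        x[_POOL_ROWS] = u
        x[_I_B] = 1.0
        return u, compiled.rates(x, light)

    u = _DEFAULT_RATIOS.copy() if u0 is None else np.asarray(u0, float).copy()
    if newton_first and u0 is not None:
        sol = root(lambda v: rhs(0.0, v), u, tol=1e-13)
        if sol.success and np.all(sol.x > -1e-15) and (
            np.max(np.abs(rhs(0.0, sol.x))) < 1e-10
        ):
            return finish(np.maximum(sol.x, 0.0))

    chunk = 200 * HOURS_PER_DAY
    t = 0.0
    for _ in range(int(max_days * HOURS_PER_DAY / chunk) + 1):
        sol = solve_ivp(rhs, (t, t + chunk), u, method="LSODA",
                        t_eval=[t + chunk - HOURS_PER_DAY, t + chunk],
                        rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"ratio subsystem integration failed: {sol.message}")
        u_prev, u = sol.y[:, 0].copy(), sol.y[:, 1].copy()
        if np.max(np.abs(u - u_prev) / np.maximum(np.abs(u), 1e-12)) < tol:
            break
        # Newton from the partially settled state often lands the equilibrium early
        trial = root(lambda v: rhs(0.0, v), u, tol=1e-13)
        if trial.success and np.all(trial.x > -1e-15) and (
            np.max(np.abs(trial.x - u) / np.maximum(np.abs(u), 1e-12)) < 0.2
        ):
            return finish(np.maximum(trial.x, 0.0))
        t += chunk
    polish = root(lambda v: rhs(0.0, v), u, tol=1e-13)
    if polish.success and np.all(polish.x > -1e-15):
        u = np.maximum(polish.x, 0.0)
    return finish(u)


def max_growth_rate(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    s: float,
    light: float = 430.0,
) -> float:
    """Maximum sustainable specific growth rate (1/d) at nitrate concentration ``s``.

    The biomass-synthesis rate at the settled pool ratios; a chemostat with
    inflow S_in washes out when D exceeds ``max_growth_rate(..., s=S_in)``.
    """
    compiled = _Compiled(network, params)
    _, alpha = _settle_ratios(compiled, s, light)
    return float(alpha[_J_MR6]) * HOURS_PER_DAY


def run_chemostat_to_steady_state(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    dilution_per_day: float,
    s_in: float = 5.0e-2,
    light: float = 430.0,
    initial: CultureState | None = None,
    tol: float = 1e-6,
    max_days: float = 2000.0,
    n_restarts: int = 2,
    seed: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-14,
    net_fixation_basis: bool = False,
) -> SteadyStateResult:
    """Find the chemostat equilibrium at one dilution rate (1/d).

    The candidate equilibrium is located through the ratio subsystem (residual
    nitrate S* solves growth(S*) = D; biomass follows from the nitrogen
    balance), then confirmed by integrating the full system until the relative
    state change over a 24 h window is below ``tol`` and polishing with a
    Newton solve.  ``n_restarts`` additional ratio-subsystem runs from random
    initial ratios check that the internal equilibrium does not depend on the
    start; their maximum relative disagreement is recorded on the result.
    Washout (D above the maximum growth rate at S_in, or biomass below floor
    during confirmation) is flagged, not raised; non-convergence within
    ``max_days`` raises with the last state attached.
    """
    if dilution_per_day < 0 or light < 0:
        raise ValueError("dilution rate and light intensity must be non-negative")
    forcing = ForcingProtocol.chemostat(dilution_per_day, s_in, light)
    compiled = _Compiled(network, params)
    d_h = dilution_per_day / HOURS_PER_DAY
    c_n = compiled.cN  # per-species N content; biomass from the N balance

    warm = {"u": None, "settled": False}
    if initial is not None and initial.B > 0:
        pools = initial.as_array()[_POOL_ROWS]
        if np.all(pools >= 0) and np.any(pools > 0):
            warm["u"] = pools / initial.B  # user guess seeds the ratio settle

    def mu_of_s(s: float) -> tuple[float, np.ndarray]:
        # first settle integrates to stationarity; later ones (continuation
        # along the nitrate bracket) may go straight to Newton
        u, alpha = _settle_ratios(
            compiled, s, light, u0=warm["u"], newton_first=warm["settled"]
        )
        warm["u"] = u
        warm["settled"] = True
        return float(alpha[_J_MR6]), u

    mu_max_h, _ = mu_of_s(s_in)
    if mu_max_h * HOURS_PER_DAY <= dilution_per_day:
        x = np.zeros(8)
        x[_I_S] = s_in
        return _equilibrium_summary(
            network, params, x, dilution_per_day, s_in, light, True,
            net_fixation_basis=net_fixation_basis,
        )

    # residual nitrate at equilibrium: growth(S*) = D
    if dilution_per_day == 0.0:
        s_star = 0.0
        u_star = mu_of_s(max(s_in * 1e-6, 1e-12))[1]
    else:
        s_star = brentq(
            lambda s: mu_of_s(s)[0] - d_h, s_in * 1e-9, s_in, rtol=1e-12,
        )
        _, u_star = mu_of_s(s_star)

    # nitrogen balance: D (S_in - S*) = N_B alpha_MR6 B  =>  B = (S_in - S*) / N_B
    n_b = c_n[_I_B]
    b_star = (s_in - s_star) / n_b
    x0 = np.zeros(8)
    x0[_I_S] = s_star
    x0[_POOL_ROWS] = u_star * b_star
    x0[_I_B] = b_star
    alpha_star = compiled.rates(x0, light)
    if network.variant.excretion_locus is not None and d_h > 0:
        j_ex = network.reaction_ids.index("MR7")
        x0[_IDX["P"]] = alpha_star[j_ex] * b_star / d_h

    x, converged, washed = _integrate_to_stationary(
        network, params, forcing, CultureState.from_array(np.maximum(x0, 0.0)),
        tol, max_days, rtol, atol,
    )
    if not converged:
        raise RuntimeError(
            f"chemostat at D={dilution_per_day}/d did not reach steady state "
            f"within {max_days} days; last state {x}"
        )
    if not washed:
        polish = root(lambda y: compiled.rhs(0.0, y, light, d_h, s_in), x, tol=1e-12)
        if polish.success and np.all(polish.x > -1e-15) and (
            np.max(np.abs(polish.x - x) / np.maximum(np.abs(x), 1e-14)) < 0.05
        ):
            x = np.maximum(polish.x, 0.0)

    result = _equilibrium_summary(
        network, params, x, dilution_per_day, s_in, light, True,
        net_fixation_basis=net_fixation_basis,
    )

    if n_restarts > 0 and not washed:
        rng = np.random.default_rng(seed)
        spread = 0.0
        for _ in range(n_restarts):
            factors = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=5))
            u_alt, _ = _settle_ratios(compiled, s_star, light, u0=u_star * factors)
            spread = max(spread, float(np.max(
                np.abs(u_alt - u_star) / np.maximum(np.abs(u_star), 1e-12)
            )))
        result.initial_condition_spread = spread
    return result


def excreted_fraction(
    network: MacroReactionNetwork,
    alpha: np.ndarray,
    net_fixation_basis: bool = False,
) -> float:
    """Excreted carbon flux as a percentage of carbon fixation.

    Default basis is gross photosynthetic fixation (3 C per MR1 turnover); with
    ``net_fixation_basis`` the CO2 respired by lipid/biomass synthesis (and by
    acetate excretion) is subtracted from the denominator.
    """
    if network.variant.excretion_locus is None:
        return 0.0
    j1 = network.reaction_ids.index("MR1")
    j_ex = network.reaction_ids.index("MR7")
    c_p = network.species_by_name("P").carbon_atoms
    fixed = 3.0 * alpha[j1]
    if net_fixation_basis:
        co2 = np.array([r.coefficient("CO2") for r in network.reactions])
        fixed = -float(co2 @ alpha)
    if fixed <= 0:
        return float("nan")
    return 100.0 * c_p * alpha[j_ex] / fixed


def sweep_dilution(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    dilutions_per_day: np.ndarray,
    **kwargs,
) -> list[SteadyStateResult]:
    """Steady states over a list of dilution rates (washouts flagged, kept)."""
    return [
        run_chemostat_to_steady_state(network, params, float(d), **kwargs)
        for d in dilutions_per_day
    ]


def quota_rate_table(results: list[SteadyStateResult]) -> pd.DataFrame:
    """Tidy (q, mu, eta, ...) table from non-washout steady states."""
    rows = [
        {
            "dilution_per_day": r.dilution_per_day,
            "q_gN_per_gC": r.nitrogen_quota,
            "mu_per_day": r.growth_rate_per_day,
            "eta_per_day": r.excretion_rate_per_day,
            "carb_quota": r.carb_quota,
            "lipid_quota": r.lipid_quota,
            "excreted_fraction_pct": r.excreted_fraction_pct,
        }
        for r in results
        if not r.washout
    ]
    return pd.DataFrame(rows)
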