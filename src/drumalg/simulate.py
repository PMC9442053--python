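"""ODE integration of the macro-reaction model under culture forcing.

The dynamic state x = (S, GAP, G6P, PEP, PA, CARB, B, P) in mol/L evolves as

    dx/dt = K' alpha(x, t) B  +  D(t) S_in(t) e_S  -  D(t) x

with K' the stoichiometric matrix restricted to the dynamic species and alpha
the vector of specific macro-reaction rates (1/h).  Day/night light kinks,
dilution/inflow steps and nitrate pulses are handled as integration
breakpoints; pulses are instantaneous state jumps.

Mass-action ratio kinetics can transiently drive a nearly-empty pool negative;
a reflecting floor (default 1e-12 mol/L) zeroes any reaction rate in the
direction that consumes an exhausted pool, which preserves element balance
exactly (whole columns of K' are switched off, never single entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .forcing import ForcingProtocol
from .network import DYNAMIC_SPECIES, MW_C, MW_N, MacroReactionNetwork
from .params import KineticParameterSet

__all__ = [
    "CultureState",
    "Trajectory",
    "SimulationError",
    "DegenerateStateError",
    "kinetic_rates",
    "ode_rhs",
    "simulate",
    "observables",
]

#: reflecting floor below which a pool is treated as exhausted (mol/L)
POOL_FLOOR = 1e-12

#: default chlorophyll content of functional biomass (g Chl per g C of B)
THETA_CHL = 0.05

_IDX = {name: i for i, name in enumerate(DYNAMIC_SPECIES)}
_I_S, _I_B = _IDX["NO3"], _IDX["B"]


class SimulationError(RuntimeError):
    """Integration failed; carries the failure time and last state."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} (t={t:.4g} h, state={np.array2string(state, precision=4)})")
        self.t = t
        self.state = state


class DegenerateStateError(ValueError):
    """Ratio kinetics evaluated at non-positive functional biomass."""


@dataclass
class CultureState:
    """Dynamic state of the culture (all in mol/L)."""

    S: float = 0.0
    GAP: float = 0.0
    G6P: float = 0.0
    PEP: float = 0.0
    PA: float = 0.0
    CARB: float = 0.0
    B: float = 0.0
    P: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.GAP, self.G6P, self.PEP,
                         self.PA, self.CARB, self.B, self.P])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "CultureState":
        return cls(*(float(v) for v in x))

    def validate(self) -> None:
        x = self.as_array()
        if np.any(x < 0):
            raise ValueError(f"negative concentration in state: {self}")
        if self.B <= 0:
            raise DegenerateStateError("functional biomass B must be positive")


class _Compiled:
    """Index-based fast evaluator for one (network, parameter set) pair."""

    def __init__(self, network: MacroReactionNetwork, params: KineticParameterSet):
        if (network.variant.excretion_locus is None) != (params.k_EX is None):
            raise ValueError(
                "k_EX must be provided exactly when the variant has the "
                f"excretion reaction (variant {network.variant.id})"
            )
        self.network = network
        self.K = np.ascontiguousarray(network.K_prime)
        self.n_rxn = network.n_reactions
        # per reaction: (kf, fwd pool indices, uses_light, uses_substrate, kr, rev pool indices)
        self.laws = []
        for rxn in network.reactions:
            law = rxn.kinetics
            kf = params[law.fwd_constant]
            kr = params[law.rev_constant] if law.rev_constant else 0.0
            self.laws.append((
                kf,
                tuple(_IDX[s] for s in law.fwd_ratios),
                law.uses_light,
                law.uses_substrate,
                kr,
                tuple(_IDX[s] for s in law.rev_ratios),
            ))
        # pools consumed by the forward (column < 0) / reverse (column > 0) direction
        self.consumed_fwd = [tuple(np.nonzero(self.K[:, j] < 0)[0]) for j in range(self.n_rxn)]
        self.consumed_rev = [tuple(np.nonzero(self.K[:, j] > 0)[0]) for j in range(self.n_rxn)]
        # net CO2 stoichiometry per reaction (for the carbon audit)
        self.co2 = np.array([r.coefficient("CO2") for r in network.reactions])
        self.cC = network.dynamic_atoms("C")
        self.cN = network.dynamic_atoms("N")

    def rates(self, x: np.ndarray, light: float, floor: float = POOL_FLOOR) -> np.ndarray:
        B = x[_I_B]
        if B < floor:
            B = floor
        alpha = np.empty(self.n_rxn)
        S = x[_I_S]
        for j, (kf, fidx, uses_light, uses_substrate, kr, ridx) in enumerate(self.laws):
            a = kf
            for i in fidx:
                a *= x[i] / B
            if uses_light:
                a *= light
            if uses_substrate:
                a *= S if S > 0.0 else 0.0
            if kr:
                r = kr
                for i in ridx:
                    r *= x[i] / B
                a -= r
            if a > 0.0:
                for i in self.consumed_fwd[j]:
                    if x[i] <= floor:
                        a = 0.0
                        break
            elif a < 0.0:
                for i in self.consumed_rev[j]:
                    if x[i] <= floor:
                        a = 0.0
                        break
            alpha[j] = a
        return alpha

    def rhs(self, t: float, x: np.ndarray, light: float, D: float, s_in: float) -> np.ndarray:
        alpha = self.rates(x, light)
        B = x[_I_B]
        dx = self.K.dot(alpha * (B if B > 0.0 else 0.0))
        dx -= D * x
        dx[_I_S] += D * s_in
        return dx

    def rhs_audited(self, t, y, light, D, s_in):
        """RHS over the augmented state [x, C fixed from CO2, C washed out, net N washed out]."""
        x = y[:8]
        alpha = self.rates(x, light)
        B = x[_I_B]
        Beff = B if B > 0.0 else 0.0
        dx = self.K.dot(alpha * Beff)
        dx -= D * x
        dx[_I_S] += D * s_in
        tc = float(self.cC @ x)
        tn = float(self.cN @ x)
        return np.concatenate([dx, [-float(self.co2 @ alpha) * Beff,
                                    D * tc,
                                    D * (tn - s_in)]])


def kinetic_rates(
    network: MacroReactionNetwork,
    state: CultureState | np.ndarray,
    params: KineticParameterSet,
    light: float,
) -> np.ndarray:
    """Specific macro-reaction rates alpha (1/h), ordered as ``network.reactions``.

    Raises :class:`DegenerateStateError` if functional biomass is not positive.
    """
    x = state.as_array() if isinstance(state, CultureState) else np.asarray(state, float)
    if x[_I_B] <= 0:
        raise DegenerateStateError("ratio kinetics require B > 0")
    return _Compiled(network, params).rates(x, light)


def ode_rhs(
    t: float,
    state: CultureState | np.ndarray,
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    forcing: ForcingProtocol,
) -> np.ndarray:
    """Time derivative of the dynamic state at time ``t`` (hours)."""
    x = state.as_array() if isinstance(state, CultureState) else np.asarray(state, float)
    return _Compiled(network, params).rhs(
        t, x, forcing.light(t), forcing.dilution(t), forcing.inflow_substrate(t)
    )


@dataclass
class Trajectory:
    """Simulated trajectory on the requested output grid (times in hours)."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 8), columns ordered as DYNAMIC_SPECIES
    network: MacroReactionNetwork
    params: KineticParameterSet
    forcing: ForcingProtocol
    alphas: np.ndarray = field(default=None)  # (n_times, n_reactions)
    audit: np.ndarray | None = None  # (n_times, 3) cumulative audit integrals
    theta_chl: float = THETA_CHL

    def __post_init__(self) -> None:
        if self.alphas is None:
            compiled = _Compiled(self.network, self.params)
            self.alphas = np.array([
                compiled.rates(x, self.forcing.light(t))
                for t, x in zip(self.times, self.states)
            ])

    def state_at(self, i: int) -> CultureState:
        return CultureState.from_array(self.states[i])

    @property
    def final_state(self) -> CultureState:
        return CultureState.from_array(self.states[-1])

    def observables(self) -> "pd.DataFrame":
        return observables(self)

    def conservation_residuals(self) -> tuple[float, float]:
        """Max relative carbon / nitrogen closure residual along the trajectory.

        Requires the run to have been made with ``audit=True``.  Carbon closure
        compares the change in total organic carbon (particulate + dissolved
        product) against net CO2 fixation minus dilution losses; nitrogen
        closure compares S + X_N against dilution and pulse accounting.
        """
        if self.audit is None:
            raise ValueError("simulate(..., audit=True) is required for closure checks")
        cC = self.network.dynamic_atoms("C")
        cN = self.network.dynamic_atoms("N")
        tc = self.states @ cC
        tn = self.states @ cN
        pulse_n = np.zeros_like(self.times)
        for t_p, species, amount in self.forcing.pulses:
            if species == "NO3":
                pulse_n[self.times > t_p] += amount
        c_resid = (tc - tc[0]) - (self.audit[:, 0] - self.audit[:, 1])
        n_resid = (tn - tn[0]) - (pulse_n - self.audit[:, 2])
        return (
            float(np.max(np.abs(c_resid)) / np.max(tc)),
            float(np.max(np.abs(n_resid)) / np.max(tn)),
        )


def simulate(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    forcing: ForcingProtocol,
    initial: CultureState,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    audit: bool = False,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the model over ``t_span`` (hours; start may be negative for warm-up).

    ``t_eval`` defaults to an hourly grid.  Forcing discontinuities (light
    kinks, dilution steps, pulses) split the integration into segments; pulse
    events are applied as instantaneous concentration jumps at their time.
    """
    initial.validate()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if t_eval is None:
        t_eval = np.arange(t0, t1 + 1e-9, 1.0)
    t_eval = np.asarray(t_eval, float)
    if t_eval[0] < t0 - 1e-9 or t_eval[-1] > t1 + 1e-9:
        raise ValueError("t_eval must lie within t_span")

    compiled = _Compiled(network, params)
    seg_edges = [t0] + forcing.breakpoints(t0, t1) + [t1]
    pulses = {t: [] for t, _, _ in forcing.pulses}
    for t, species, amount in forcing.pulses:
        pulses[t].append((species, amount))

    x = initial.as_array()
    if audit:
        x = np.concatenate([x, np.zeros(3)])
    out_t: list[float] = []
    out_x: list[np.ndarray] = []
    # grid points exactly at t0 are recorded from the initial state
    mask0 = np.isclose(t_eval, t0, rtol=0.0, atol=1e-9)
    for _ in range(int(mask0.sum())):
        out_t.append(t0)
        out_x.append(x.copy())

    rhs = compiled.rhs_audited if audit else compiled.rhs
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        # constant dilution/inflow within the segment; light varies smoothly
        mid = 0.5 * (a + b)
        D = forcing.dilution(mid)
        s_in = forcing.inflow_substrate(mid)
        seg_eval = t_eval[(t_eval > a + 1e-12) & (t_eval <= b - 1e-12)]
        sol = solve_ivp(
            lambda t, y: rhs(t, y, forcing.light(t), D, s_in),
            (a, b), x, method=method,
            t_eval=np.unique(np.concatenate([seg_eval, [b]])),
            rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed: {sol.message}", sol.t[-1] if len(sol.t) else a, x[:8])
        for tt, yy in zip(sol.t, sol.y.T):
            if tt < b - 1e-12:
                out_t.append(tt)
                out_x.append(yy.copy())
        x = sol.y[:, -1].copy()
        # grid points at the segment end are recorded before any pulse jump
        at_b = np.isclose(t_eval, b, rtol=0.0, atol=1e-9) & ~mask0
        for _ in range(int(at_b.sum())):
            out_t.append(b)
            out_x.append(x.copy())
        if b in pulses:
            for species, amount in pulses[b]:
                x[_IDX[species]] += amount

    states = np.array(out_x)
    traj = Trajectory(
        times=np.array(out_t),
        states=states[:, :8],
        network=network,
        params=params,
        forcing=forcing,
        audit=states[:, 8:] if audit else None,
    )
    return traj


def observables(trajectory: Trajectory) -> "pd.DataFrame":
    """Derived measurement-comparable observables along a trajectory.

    Returns a tidy frame with one row per time point:

    - ``XC_molC_per_L`` / ``XC_gC_per_L``: particulate organic carbon
      (accumulating pools + functional biomass; the dissolved excreted product
      is counted separately as ``P_molC_per_L``),
    - ``XN_molN_per_L`` / ``XN_gN_per_L``: particulate organic nitrogen,
    - ``chlorophyll_g_per_L``: theta_chl x carbon mass of functional biomass,
    - ``carb_quota`` / ``lipid_quota``: carbohydrate and neutral-lipid carbon
      as fractions of X_C (gC/gC),
    - ``NC_quota_gN_per_gC``: nitrogen:carbon quota,
    - ``nitrate_molN_per_L``,
    - ``excretion_molC_per_L_h``: instantaneous excreted-carbon flux.
    """
    import pandas as pd

    net = trajectory.network
    cC = net.dynamic_atoms("C")
    cN = net.dynamic_atoms("N")
    x = trajectory.states
    c_b = net.species_by_name("B").carbon_atoms

    part = [i for i, sp in enumerate(DYNAMIC_SPECIES) if sp not in ("NO3", "P")]
    xc = x[:, part] @ cC[part]
    xn = x[:, part] @ cN[part]
    b = x[:, _I_B]
    carb = net.species_by_name("CARB").carbon_atoms * x[:, _IDX["CARB"]]
    if net.variant.excretion_locus is not None:
        c_p = net.species_by_name("P").carbon_atoms
        j_ex = net.reaction_ids.index("MR7")
        excretion = c_p * trajectory.alphas[:, j_ex] * b
        p_c = c_p * x[:, _IDX["P"]]
    else:
        excretion = np.zeros_like(xc)
        p_c = np.zeros_like(xc)
    pa_c = net.species_by_name("PA").carbon_atoms * x[:, _IDX["PA"]]

    with np.errstate(divide="ignore", invalid="ignore"):
        carb_quota = np.where(xc > 0, carb / xc, 0.0)
        lipid_quota = np.where(xc > 0, pa_c / xc, 0.0)
        nc = np.where(xc > 0, (xn * MW_N) / (xc * MW_C), 0.0)

    return pd.DataFrame({
        "time_h": trajectory.times,
        "XC_molC_per_L": xc,
        "XN_molN_per_L": xn,
        "XC_gC_per_L": xc * MW_C,
        "XN_gN_per_L": xn * MW_N,
        "chlorophyll_g_per_L": trajectory.theta_chl * c_b * b * MW_C,
        "carb_quota": carb_quota,
        "lipid_quota": lipid_quota,
        "NC_quota_gN_per_gC": nc,
        "nitrate_molN_per_L": x[:, _I_S],
        "P_molC_per_L": p_c,
        "excretion_molC_per_L_h": excretion,
    })
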