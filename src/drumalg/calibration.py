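"""Parameter estimation, uncertainty quantification and model comparison.

Kinetic parameters are estimated by minimising a scaled sum of squared errors
between simulated observables and measurements, with multistart Nelder-Mead in
log10 parameter space (mass-action rate constants are positive and span
decades).  Box constraints — notably the quantum-limit cap on the
photosynthetic constant — are enforced by a smooth quadratic penalty so the
simplex remains well-behaved near bounds.

Uncertainty comes from the Fisher information matrix built from
finite-difference output sensitivities; variants with different parameter
counts are compared with the small-sample corrected Akaike criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .forcing import ForcingProtocol
from .network import MacroReactionNetwork
from .params import K_MR1_QUANTUM_LIMIT, KineticParameterSet
from .simulate import CultureState, Trajectory, observables, simulate

__all__ = [
    "OBSERVABLE_COLUMNS",
    "MeasurementSet",
    "CalibrationResult",
    "simulate_observations",
    "weighted_sse",
    "fit_parameters",
    "fisher_information",
    "parameter_std",
    "output_uncertainty",
    "aicc",
    "percent_improvement",
    "infer_sample_size",
    "DEFAULT_BOUNDS",
]

#: measurement observable name -> column of :func:`drumalg.simulate.observables`
OBSERVABLE_COLUMNS = {
    "XC": "XC_gC_per_L",
    "XN": "XN_gN_per_L",
    "chlorophyll": "chlorophyll_g_per_L",
    "carb_quota": "carb_quota",
    "lipid_quota": "lipid_quota",
    "nitrate": "nitrate_molN_per_L",
}

# order-of-magnitude prior ranges for the rate constants (hourly basis),
# bracketing the spread of published estimates across model variants
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_MR1": (1e-4, K_MR1_QUANTUM_LIMIT),
    "k_MR2": (1e-2, 1e4),
    "k_MR2p": (1e-3, 1e2),
    "k_MR3": (1e0, 1e5),
    "k_MR3p": (1e-1, 1e4),
    "k_MR4": (1e-1, 1e5),
    "k_MR4p": (1e-4, 1e3),
    "k_MR5": (1e-3, 1e3),
    "k_MR5p": (1e-3, 1e0),
    "k_MR6": (1e1, 1e6),
    "k_EX": (1e-3, 1e1),
}

_PENALTY_WEIGHT = 1e6


@dataclass
class MeasurementSet:
    """Measurement time series plus the forcing protocol that produced them.

    ``data`` columns: ``time_h``, ``observable`` (one of
    :data:`OBSERVABLE_COLUMNS`), ``value``, and optional ``sd`` (> 0 where
    present; used as the residual scale).  ``initial`` and ``warmup_h`` define
    where the simulation starts: ``warmup_h`` hours before the first
    measurement, so the trajectory on the measured window does not depend on
    the initial condition.
    """

    data: pd.DataFrame
    protocol: ForcingProtocol
    initial: CultureState
    warmup_h: float = 120.0
    theta_chl: float = 0.05

    def __post_init__(self) -> None:
        required = {"time_h", "observable", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
        unknown = set(self.data["observable"]) - set(OBSERVABLE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown observables: {sorted(unknown)}")
        if "sd" in self.data.columns:
            sd = self.data["sd"].dropna()
            if (sd <= 0).any():
                raise ValueError("measurement standard deviations must be > 0")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def scales(self) -> np.ndarray:
        """Per-observation residual scale: sd where given, else the observable's mean."""
        values = self.data["value"].to_numpy(float)
        scale = np.empty(len(values))
        sd = self.data["sd"].to_numpy(float) if "sd" in self.data.columns else np.full(len(values), np.nan)
        for name, grp in self.data.groupby("observable"):
            idx = grp.index.to_numpy()
            mean_scale = float(np.mean(np.abs(values[idx])))
            if mean_scale == 0.0:
                mean_scale = 1.0
            grp_sd = sd[idx]
            scale[idx] = np.where(np.isfinite(grp_sd) & (grp_sd > 0), grp_sd, mean_scale)
        return scale

    def restricted_to(self, t_max_h: float) -> "MeasurementSet":
        """Copy keeping only measurements at or before ``t_max_h`` (e.g., the
        nitrogen-replete first day used for the no-excretion calibration)."""
        return MeasurementSet(
            self.data[self.data["time_h"] <= t_max_h].copy(),
            self.protocol, self.initial, self.warmup_h, self.theta_chl,
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def simulate_observations(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    data: MeasurementSet,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    return_trajectory: bool = False,
):
    """Model predictions at every (time, observable) measurement row."""
    times = np.unique(data.data["time_h"].to_numpy(float))
    t0 = float(times[0]) - data.warmup_h
    traj = simulate(
        network, params, data.protocol, data.initial,
        (t0, float(times[-1])), t_eval=times, rtol=rtol, atol=atol,
    )
    traj.theta_chl = data.theta_chl
    obs = observables(traj)
    obs = obs.drop_duplicates(subset="time_h", keep="last").set_index("time_h")
    pred = np.empty(data.n_obs)
    t_arr = data.data["time_h"].to_numpy(float)
    o_arr = data.data["observable"].to_numpy()
    for k in range(data.n_obs):
        pred[k] = obs.at[t_arr[k], OBSERVABLE_COLUMNS[o_arr[k]]]
    if return_trajectory:
        return pred, traj
    return pred


def weighted_sse(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    data: MeasurementSet,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> float:
    """Scaled sum of squared errors between simulation and measurements."""
    try:
        pred = simulate_observations(network, params, data, rtol=rtol, atol=atol)
    except Exception as exc:
        raise RuntimeError(f"simulation failed at parameters {params.as_dict()}") from exc
    resid = (pred - data.data["value"].to_numpy(float)) / data.scales()
    return float(resid @ resid)


@dataclass
class CalibrationResult:
    """Results of a calibration run (statsmodels-style results object)."""

    network: MacroReactionNetwork
    params: KineticParameterSet  # full parameter set at the optimum
    fitted_names: list[str]
    sse: float
    n_obs: int
    multistart_record: list[dict] = field(default_factory=list)
    fim: np.ndarray | None = None
    sigma: np.ndarray | None = None
    fim_pinv_used: bool = False

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[name] for name in self.fitted_names])

    @property
    def n_params(self) -> int:
        return len(self.fitted_names)

    @property
    def aicc(self) -> float | None:
        if self.n_obs <= self.n_params + 2:
            return None
        return aicc(self.sse, self.n_obs, self.n_params)

    def conf_int(self, z: float = 1.96) -> pd.DataFrame:
        if self.sigma is None:
            raise ValueError("no uncertainty available; fit with compute_uncertainty=True")
        theta = self.theta
        return pd.DataFrame({
            "parameter": self.fitted_names,
            "estimate": theta,
            "sd": self.sigma,
            "lower": theta - z * self.sigma,
            "upper": theta + z * self.sigma,
        })

    def summary(self) -> str:
        lines = [
            f"Calibration of variant {self.network.variant.id}",
            f"  observations: {self.n_obs}   fitted parameters: {self.n_params}",
            f"  SSE: {self.sse:.6g}" + (f"   AICc: {self.aicc:.1f}" if self.aicc is not None else ""),
            "",
            f"  {'parameter':<10} {'estimate':>12} {'std dev':>12}",
        ]
        sigma = self.sigma if self.sigma is not None else [float("nan")] * self.n_params
        for name, est, sd in zip(self.fitted_names, self.theta, sigma):
            lines.append(f"  {name:<10} {est:>12.4g} {sd:>12.4g}")
        return "\n".join(lines)


def _make_objective(network, base_params, data, fit_names, bounds, rtol, atol):
    lo = np.array([bounds[n][0] for n in fit_names])
    hi = np.array([bounds[n][1] for n in fit_names])

    def to_params(theta: np.ndarray) -> KineticParameterSet:
        values = {n: float(max(v, 0.0)) for n, v in zip(fit_names, theta)}
        if "k_MR1" in values:
            # hard physical cap; the penalty term handles the excursion itself
            values["k_MR1"] = min(values["k_MR1"], K_MR1_QUANTUM_LIMIT)
        return base_params.updated(**values)

    def objective(phi: np.ndarray) -> float:
        theta = 10.0 ** phi
        over = np.maximum(0.0, (theta - hi) / hi)
        under = np.maximum(0.0, (lo - theta) / lo)
        penalty = _PENALTY_WEIGHT * float(over @ over + under @ under)
        try:
            # k_MR1 stays evaluable below its hard cap during penalised excursions
            sse = weighted_sse(network, _clip_quantum(to_params(theta)), data, rtol=rtol, atol=atol)
        except RuntimeError:
            return 1e12 + penalty
        return sse + penalty

    return objective, to_params, lo, hi


def _clip_quantum(params: KineticParameterSet) -> KineticParameterSet:
    if params.k_MR1 > K_MR1_QUANTUM_LIMIT:
        return params.updated(k_MR1=K_MR1_QUANTUM_LIMIT)
    return params


def fit_parameters(
    network: MacroReactionNetwork,
    data: MeasurementSet,
    base_params: KineticParameterSet,
    fit_names: list[str] | None = None,
    n_starts: int = 3,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    start: KineticParameterSet | None = None,
    compute_uncertainty: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    maxfev: int | None = None,
    xatol: float = 1e-4,
    fatol: float = 1e-10,
) -> CalibrationResult:
    """Multistart Nelder-Mead estimation of the kinetic parameters.

    ``fit_names`` selects the subset of parameters to estimate (default: all
    constants of the variant); the remaining ones stay at ``base_params``.
    Starts are drawn log-uniformly within ``bounds``; if ``start`` is given it
    seeds the first start.  Per-start seeds derive deterministically from
    ``seed``, so a fit is fully reproducible.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    fit_names = fit_names or base_params.names()
    all_bounds = dict(DEFAULT_BOUNDS)
    all_bounds.update(bounds or {})
    objective, to_params, lo, hi = _make_objective(
        network, base_params, data, fit_names, all_bounds, rtol, atol
    )

    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    record: list[dict] = []
    best = None
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if i == 0 and start is not None:
            phi0 = np.log10(np.array([start[n] for n in fit_names]))
        else:
            phi0 = rng.uniform(np.log10(lo), np.log10(hi))
        res = minimize(
            objective, phi0, method="Nelder-Mead",
            options={
                "xatol": xatol, "fatol": fatol,
                "maxfev": maxfev or 400 * len(fit_names),
            },
        )
        record.append({
            "start": i,
            "seed_entropy": ss.entropy,
            "objective": float(res.fun),
            "nfev": int(res.nfev),
            "success": bool(res.success),
        })
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {n_starts} optimisation starts failed: {record}")

    theta_best = np.minimum(10.0 ** best.x, hi)
    params_hat = _clip_quantum(to_params(theta_best))
    sse = weighted_sse(network, params_hat, data, rtol=rtol, atol=atol)
    result = CalibrationResult(
        network=network,
        params=params_hat,
        fitted_names=list(fit_names),
        sse=sse,
        n_obs=data.n_obs,
        multistart_record=record,
    )
    if compute_uncertainty:
        fim = fisher_information(network, params_hat, data, fit_names, rtol=rtol, atol=atol)
        sigma, pinv_used = parameter_std(fim, return_flag=True)
        result.fim = fim
        result.sigma = sigma
        result.fim_pinv_used = pinv_used
    return result


def _sensitivities(
    network, params, data, fit_names, rel_step=1e-4, rtol=1e-6, atol=1e-10
) -> np.ndarray:
    """Central finite-difference sensitivities d pred / d theta, shape (n_obs, p)."""
    J = np.empty((data.n_obs, len(fit_names)))
    for j, name in enumerate(fit_names):
        theta = params[name]
        h = rel_step * theta if theta != 0 else rel_step
        theta_lo = max(theta - h, 0.0)
        hi = simulate_observations(network, params.updated(**{name: theta + h}), data, rtol, atol)
        lo = simulate_observations(network, params.updated(**{name: theta_lo}), data, rtol, atol)
        J[:, j] = (hi - lo) / (theta + h - theta_lo)
    return J


def fisher_information(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    data: MeasurementSet,
    fit_names: list[str],
    rel_step: float = 1e-4,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> np.ndarray:
    """FIM = J^T W J with W the diagonal measurement precision (1/scale^2)."""
    J = _sensitivities(network, params, data, fit_names, rel_step, rtol, atol)
    w = 1.0 / data.scales() ** 2
    return (J * w[:, None]).T @ J


def parameter_std(fim: np.ndarray, return_flag: bool = False):
    """Per-parameter standard deviations sqrt(diag(FIM^-1)).

    Falls back to the Moore-Penrose pseudo-inverse for singular matrices;
    parameters whose (pseudo-)variance is negative are flagged non-identifiable
    and reported as NaN.
    """
    fim = np.asarray(fim, float)
    if fim.ndim == 0:
        fim = fim.reshape(1, 1)
    pinv_used = False
    try:
        cov = np.linalg.inv(fim)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fim)
        pinv_used = True
    diag = np.diag(cov).copy()
    sigma = np.where(diag >= 0, np.sqrt(np.abs(diag)), np.nan)
    if return_flag:
        return sigma, pinv_used
    return sigma


def output_uncertainty(
    network: MacroReactionNetwork,
    params: KineticParameterSet,
    sigma: np.ndarray,
    data: MeasurementSet,
    fit_names: list[str],
    rel_step: float = 1e-4,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    z: float = 1.96,
) -> pd.DataFrame:
    """First-order error propagation onto the model outputs at the data grid.

    sigma_y^2(t) = sum_j (d y / d theta_j)^2 sigma_j^2 (parameter covariances
    deliberately ignored, which understates the true output uncertainty); the
    returned bands are y +/- z sigma_y.
    """
    pred = simulate_observations(network, params, data, rtol, atol)
    J = _sensitivities(network, params, data, fit_names, rel_step, rtol, atol)
    var = (J ** 2) @ (np.asarray(sigma, float) ** 2)
    sd = np.sqrt(var)
    out = data.data[["time_h", "observable"]].copy()
    out["prediction"] = pred
    out["sd"] = sd
    out["lower"] = pred - z * sd
    out["upper"] = pred + z * sd
    return out


def aicc(sse: float, n: int, p: int) -> float:
    """Corrected Akaike information criterion for least-squares fits.

    AICc = n ln(SSE/n) + 2(p+1) + 2(p+1)(p+2)/(n-p-2), natural logarithm.
    Undefined (raises) unless n > p + 2.
    """
    if n <= p + 2:
        raise ValueError(f"AICc undefined for n={n} <= p+2={p + 2}")
    if sse <= 0:
        raise ValueError("SSE must be positive")
    return n * np.log(sse / n) + 2 * (p + 1) + 2 * (p + 1) * (p + 2) / (n - p - 2)


def percent_improvement(sse_ref: float, sse: float) -> float:
    """100 x (sse_ref - sse) / sse_ref, rounded to one decimal for reporting."""
    if sse_ref <= 0:
        raise ValueError("reference SSE must be positive")
    return round(100.0 * (sse_ref - sse) / sse_ref, 1)


def infer_sample_size(
    rows: list[tuple[float, int, int]],
    n_range: tuple[int, int] = (50, 1000),
) -> list[int]:
    """Integer sample sizes consistent with reported (SSE, p, AICc) rows.

    Returns every n in ``n_range`` for which the AICc formula maps each row's
    (SSE, p) to its reported integer-rounded AICc — a consistency oracle for a
    measurement count that is not reported directly.
    """
    consistent = []
    for n in range(n_range[0], n_range[1] + 1):
        ok = True
        for sse, p, reported in rows:
            if n <= p + 2 or round(aicc(sse, n, p)) != reported:
                ok = False
                break
        if ok:
            consistent.append(n)
    return consistent
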