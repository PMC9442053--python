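"""Synthetic measurement datasets emulating the two culture experiments.

Two experiment layouts are generated from the model itself:

* ``day_night_starvation`` — an 8-day 12h:12h day/night culture peaking at
  1500 umol m-2 s-1, nitrogen-starved from day 1 to day 5.5 and refed with a
  2.7 mgN/L nitrate pulse, sampled for particulate C and N, chlorophyll,
  storage quotas and nitrate;
* ``chemostat_sweep`` — constant-light (430 umol m-2 s-1) nitrogen-limited
  chemostats over a range of dilution rates, exporting steady-state quota and
  rate tables.

Measurement noise is multiplicative Gaussian with a configurable coefficient
of variation (these assays' errors scale with magnitude), truncated at zero.
The reported ``sd`` column is CV times the noiseless value, i.e. the true
measurement scale.  Default sampling is every 3 h within the photoperiod plus
one night sample.  Everything is reproducible from the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import OBSERVABLE_COLUMNS, MeasurementSet
from .chemostat import SteadyStateResult, quota_rate_table, sweep_dilution
from .forcing import HOURS_PER_DAY, ForcingProtocol
from .network import MacroReactionNetwork, build_variant
from .params import KineticParameterSet, reference_parameters
from .simulate import CultureState, observables, simulate

__all__ = [
    "DAY_NIGHT_INITIAL",
    "SyntheticProtocolSpec",
    "default_sampling_times",
    "generate_calibration_dataset",
    "generate_chemostat_dataset",
]

#: nominal pre-experiment state: the dawn state of the nitrogen-replete
#: periodic regime of the default day/night chemostat (D = 0.25/d,
#: S_in = 2 mM); a documented stand-in, not a claim about any real culture
DAY_NIGHT_INITIAL = CultureState(
    S=5.7e-4, GAP=2.4e-5, G6P=1.1e-5, PEP=3.5e-4, PA=1.8e-4, CARB=3.2e-3,
    B=1.1e-3, P=0.0,
)


def default_sampling_times(
    n_days: int = 8, photoperiod_h: float = 12.0, every_h: float = 3.0
) -> np.ndarray:
    """Sampling grid: every ``every_h`` within each photoperiod plus one night point."""
    times = []
    for day in range(n_days):
        t0 = day * HOURS_PER_DAY
        s = every_h / 2.0
        while s < photoperiod_h:
            times.append(t0 + s)
            s += every_h
        times.append(t0 + photoperiod_h + (HOURS_PER_DAY - photoperiod_h) / 2.0)
    return np.array(times)


@dataclass
class SyntheticProtocolSpec:
    """Configuration of one synthetic dataset."""

    experiment: str  # day_night_starvation | chemostat_sweep
    variant: str = "ExCARB"
    true_params: KineticParameterSet | None = None
    noise_cv: float = 0.05
    sampling_times: np.ndarray | None = None
    seed: int = 0
    warmup_h: float = 120.0
    initial: CultureState = field(default_factory=lambda: DAY_NIGHT_INITIAL)

    def __post_init__(self) -> None:
        if self.experiment not in ("day_night_starvation", "chemostat_sweep"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.true_params is None:
            self.true_params = reference_parameters(self.variant)

    def network(self) -> MacroReactionNetwork:
        return build_variant(self.variant)

    def provenance(self) -> dict:
        return {
            "experiment": self.experiment,
            "variant": self.variant,
            "true_params": self.true_params.as_dict(),
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "warmup_h": self.warmup_h,
            "initial": self.initial.as_array().tolist(),
        }


def generate_calibration_dataset(
    spec: SyntheticProtocolSpec,
    protocol: ForcingProtocol | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> MeasurementSet:
    """Noisy measurement table from the day/night starvation protocol.

    Simulates from ``-warmup_h`` so the measured window sits on the periodic
    regime, samples all six observables at the spec's sampling times, and
    applies multiplicative Gaussian noise of the given CV (truncated at 0).
    """
    if spec.experiment != "day_night_starvation":
        raise ValueError("spec.experiment must be 'day_night_starvation'")
    protocol = protocol or ForcingProtocol.day_night_starvation()
    times = spec.sampling_times
    if times is None:
        times = default_sampling_times()
    times = np.asarray(times, float)

    traj = simulate(
        spec.network(), spec.true_params, protocol, spec.initial,
        (float(times[0]) - spec.warmup_h, float(times[-1])),
        t_eval=times, rtol=rtol, atol=atol,
    )
    obs = observables(traj).drop_duplicates(subset="time_h", keep="last")

    rng = np.random.default_rng(spec.seed)
    rows = []
    for name, column in OBSERVABLE_COLUMNS.items():
        truth = obs[column].to_numpy(float)
        if spec.noise_cv > 0:
            values = np.maximum(truth * (1.0 + spec.noise_cv * rng.standard_normal(len(truth))), 0.0)
            sd = np.maximum(spec.noise_cv * np.abs(truth), 1e-30)
        else:
            values = truth
            sd = np.full(len(truth), np.nan)
        for t, v, s in zip(obs["time_h"], values, sd):
            rows.append({"time_h": t, "observable": name, "value": v, "sd": s})
    data = pd.DataFrame(rows)
    return MeasurementSet(
        data=data, protocol=protocol, initial=spec.initial, warmup_h=spec.warmup_h
    )


def generate_chemostat_dataset(
    spec: SyntheticProtocolSpec,
    dilutions_per_day: np.ndarray | None = None,
    s_in: float = 5.0e-2,
    light: float = 430.0,
    **sweep_kwargs,
) -> tuple[pd.DataFrame, list[SteadyStateResult]]:
    """Steady-state quota/rate table over a dilution sweep (washouts excluded).

    Returns the tidy table (columns ``q_gN_per_gC``, ``mu_per_day``,
    ``eta_per_day``, storage quotas, excreted fraction) plus the raw
    steady-state results including any washout-flagged runs.  With
    ``noise_cv > 0``, multiplicative noise is applied to the measured columns
    (not to the imposed dilution rate).
    """
    if spec.experiment != "chemostat_sweep":
        raise ValueError("spec.experiment must be 'chemostat_sweep'")
    if dilutions_per_day is None:
        dilutions_per_day = np.array([0.02, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4])
    dilutions_per_day = np.asarray(dilutions_per_day, float)
    if np.any(dilutions_per_day <= 0) or np.any(dilutions_per_day > 1.4):
        raise ValueError("dilution rates must lie in (0, 1.4] 1/d")

    results = sweep_dilution(
        spec.network(), spec.true_params, dilutions_per_day,
        s_in=s_in, light=light, **sweep_kwargs,
    )
    table = quota_rate_table(results)
    if spec.noise_cv > 0 and len(table):
        rng = np.random.default_rng(spec.seed)
        for col in ("q_gN_per_gC", "eta_per_day", "carb_quota", "lipid_quota"):
            vals = table[col].to_numpy(float)
            table[col] = np.maximum(
                vals * (1.0 + spec.noise_cv * rng.standard_normal(len(vals))), 0.0
            )
    return table, results
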