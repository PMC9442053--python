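"""Validated run configuration (YAML/JSON) for the command-line interface.

Schemas are strict: unknown keys are rejected with field-level messages before
any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .forcing import ForcingProtocol
from .network import VARIANTS
from .params import KineticParameterSet, reference_parameters
from .simulate import CultureState
from .synthetic import DAY_NIGHT_INITIAL

__all__ = [
    "SolverConfig", "ForcingConfig", "SimulateConfig", "FitConfig",
    "SteadyStateConfig", "SynthConfig", "DroopFitConfig", "load_config",
    "config_provenance",
]

_PARAM_NAMES = {"k_MR1", "k_MR2", "k_MR2p", "k_MR3", "k_MR3p",
                "k_MR4", "k_MR4p", "k_MR5", "k_MR5p", "k_MR6", "k_EX"}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SolverConfig(_Strict):
    rtol: float = 1e-8
    atol: float = 1e-12
    method: str = "LSODA"


class ForcingConfig(_Strict):
    kind: str = "day_night_starvation"  # or "chemostat"
    # day/night starvation protocol
    i_max: float = 1500.0
    photoperiod_h: float = 12.0
    d_replete_per_day: float = 0.25
    d_starved_per_day: float = 0.1
    s_in_replete: float = 2.0e-3
    starvation_start_day: float = 1.0
    pulse_day: float = 5.5
    pulse_mgN_per_L: float = 2.7
    # constant-light chemostat
    dilution_per_day: float = 0.4
    s_in: float = 5.0e-2
    light: float = 430.0

    @model_validator(mode="after")
    def _check_kind(self):
        if self.kind not in ("day_night_starvation", "chemostat"):
            raise ValueError("forcing.kind must be 'day_night_starvation' or 'chemostat'")
        return self

    def build(self) -> ForcingProtocol:
        if self.kind == "chemostat":
            return ForcingProtocol.chemostat(self.dilution_per_day, self.s_in, self.light)
        return ForcingProtocol.day_night_starvation(
            i_max=self.i_max, photoperiod_h=self.photoperiod_h,
            d_replete_per_day=self.d_replete_per_day,
            d_starved_per_day=self.d_starved_per_day,
            s_in_replete=self.s_in_replete,
            starvation_start_day=self.starvation_start_day,
            pulse_day=self.pulse_day, pulse_mgN_per_L=self.pulse_mgN_per_L,
        )


def _build_params(variant: str, values: dict[str, float] | None) -> KineticParameterSet:
    if values is None:
        return reference_parameters(variant)
    unknown = set(values) - _PARAM_NAMES
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    has_ex = variant != "w/oEx"
    if not has_ex and "k_EX" in values:
        raise ValueError("k_EX is not a parameter of the w/oEx variant")
    if has_ex and "k_EX" not in values:
        raise ValueError(f"variant {variant} requires k_EX")
    missing = (_PARAM_NAMES - {"k_EX"}) - set(values)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    return KineticParameterSet(**values)


class _VariantRun(_Strict):
    variant: str = "ExCARB"
    params: dict[str, float] | None = None  # None -> reference estimates
    solver: SolverConfig = Field(default_factory=SolverConfig)
    seed: int = 0
    verbosity: int = 1

    @model_validator(mode="after")
    def _check(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}")
        _build_params(self.variant, self.params)  # validate eagerly
        return self

    def build_params(self) -> KineticParameterSet:
        return _build_params(self.variant, self.params)


class SimulateConfig(_VariantRun):
    forcing: ForcingConfig = Field(default_factory=ForcingConfig)
    t_start_h: float = -120.0
    t_end_h: float = 192.0
    dt_h: float = 1.0
    initial: dict[str, float] | None = None  # None -> nominal day/night state
    theta_chl: float = 0.05
    audit: bool = True

    def build_initial(self) -> CultureState:
        if self.initial is None:
            return DAY_NIGHT_INITIAL
        return CultureState(**self.initial)


class FitConfig(_VariantRun):
    forcing: ForcingConfig = Field(default_factory=ForcingConfig)
    fit_names: list[str] | None = None
    n_starts: int = 3
    bounds: dict[str, tuple[float, float]] | None = None
    warmup_h: float = 120.0
    window_end_h: float | None = None  # restrict to early measurements (e.g. first day)
    initial: dict[str, float] | None = None
    fit_rtol: float = 1e-6
    fit_atol: float = 1e-10

    def build_initial(self) -> CultureState:
        if self.initial is None:
            return DAY_NIGHT_INITIAL
        return CultureState(**self.initial)


class SteadyStateConfig(_VariantRun):
    dilutions_per_day: list[float] = Field(default_factory=lambda: [0.1, 0.4, 0.7, 1.0])
    s_in: float = 5.0e-2
    light: float = 430.0
    n_restarts: int = 2
    tol: float = 1e-6


class SynthConfig(_VariantRun):
    experiment: str = "day_night_starvation"
    noise_cv: float = 0.05
    forcing: ForcingConfig = Field(default_factory=ForcingConfig)
    dilutions_per_day: list[float] = Field(
        default_factory=lambda: [0.02, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4]
    )
    s_in: float = 5.0e-2
    light: float = 430.0


class DroopFitConfig(_Strict):
    fit_eta: bool = True
    seed: int = 0
    verbosity: int = 1


def load_config(path: str | Path, schema):
    """Load and validate a YAML/JSON config file against a schema class."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    return schema.model_validate(raw)


def config_provenance(config: BaseModel, seed: int | None = None) -> dict:
    """Machine-readable provenance block for run outputs."""
    from . import __version__

    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config.model_dump(),
        "seed": seed if seed is not None else getattr(config, "seed", None),
    }
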