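"""Kinetic parameter sets and reference estimates.

All rate constants are on an hourly basis.  ``k_MR1`` multiplies the light
intensity (umol photons m-2 s-1) and is bounded above by the quantum limit of
photosynthesis (absorption coefficient 16 m2/gChl and 10 photons per fixed
carbon give 4.5e-3 uE-1 m2 s h-1 molB-1).  Intracellular pool ratios A/B are
dimensionless, so every k times a ratio product is a specific rate in 1/h;
``k_MR6`` additionally multiplies the extracellular nitrate concentration
(mol/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "K_MR1_QUANTUM_LIMIT",
    "KineticParameterSet",
    "reference_parameters",
    "REFERENCE_ESTIMATES",
    "REFERENCE_STD",
]

#: quantum-limit upper bound on the photosynthetic rate constant
K_MR1_QUANTUM_LIMIT = 4.5e-3


@dataclass(frozen=True)
class KineticParameterSet:
    """Rate constants of the macro-reaction kinetics (hourly basis).

    ``k_EX`` must be set if and only if the network variant carries the
    excretion reaction MR7.
    """

    k_MR1: float
    k_MR2: float
    k_MR2p: float
    k_MR3: float
    k_MR3p: float
    k_MR4: float
    k_MR4p: float
    k_MR5: float
    k_MR5p: float
    k_MR6: float
    k_EX: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.k_MR1 > K_MR1_QUANTUM_LIMIT * (1 + 1e-12):
            raise ValueError(
                f"k_MR1={self.k_MR1} exceeds the quantum limit {K_MR1_QUANTUM_LIMIT}"
            )

    def as_dict(self) -> dict[str, float | None]:
        return {
            "k_MR1": self.k_MR1, "k_MR2": self.k_MR2, "k_MR2p": self.k_MR2p,
            "k_MR3": self.k_MR3, "k_MR3p": self.k_MR3p,
            "k_MR4": self.k_MR4, "k_MR4p": self.k_MR4p,
            "k_MR5": self.k_MR5, "k_MR5p": self.k_MR5p,
            "k_MR6": self.k_MR6, "k_EX": self.k_EX,
        }

    def __getitem__(self, name: str) -> float:
        value = self.as_dict()[name]
        if value is None:
            raise KeyError(f"parameter {name} is unset for this variant")
        return value

    def updated(self, **changes: float) -> "KineticParameterSet":
        return replace(self, **changes)

    def names(self, with_excretion: bool | None = None) -> list[str]:
        base = ["k_MR1", "k_MR2", "k_MR2p", "k_MR3", "k_MR3p",
                "k_MR4", "k_MR4p", "k_MR5", "k_MR5p", "k_MR6"]
        has_ex = self.k_EX is not None if with_excretion is None else with_excretion
        return base + (["k_EX"] if has_ex else [])


# Reference least-squares estimates for T. lutea, per model variant, from the
# day/night nitrogen-starvation calibration (values converted to natural
# hourly units; w/oEx was calibrated on the nitrogen-replete first day only,
# w/oEx* on the full experiment).
REFERENCE_ESTIMATES: dict[str, KineticParameterSet] = {
    "w/oEx": KineticParameterSet(
        k_MR1=1.30e-3, k_MR2=205.0, k_MR2p=0.216, k_MR3=8.10e3, k_MR3p=11.9,
        k_MR4=16.8, k_MR4p=0.0, k_MR5=55.9, k_MR5p=39.3e-3, k_MR6=11.5e3,
    ),
    "w/oEx*": KineticParameterSet(
        k_MR1=1.10e-3, k_MR2=62.6, k_MR2p=0.0, k_MR3=7.70e3, k_MR3p=321.0,
        k_MR4=13.5, k_MR4p=0.0, k_MR5=141.0, k_MR5p=43.1e-3, k_MR6=317e3,
    ),
    "ExCARB": KineticParameterSet(
        k_MR1=1.61e-3, k_MR2=6.07, k_MR2p=0.092, k_MR3=7.96e3, k_MR3p=547.0,
        k_MR4=13.6, k_MR4p=0.0, k_MR5=0.783, k_MR5p=120e-3, k_MR6=2.89e3,
        k_EX=0.0778,
    ),
    "ExG6P": KineticParameterSet(
        k_MR1=2.11e-3, k_MR2=3.32, k_MR2p=0.0, k_MR3=0.347e3, k_MR3p=122.0,
        k_MR4=46.2, k_MR4p=1.21, k_MR5=0.413, k_MR5p=117e-3, k_MR6=1.34e3,
        k_EX=5.90,
    ),
    "ExPEP": KineticParameterSet(
        k_MR1=4.50e-3, k_MR2=569.0, k_MR2p=3.04, k_MR3=5.17e3, k_MR3p=0.0,
        k_MR4=13400.0, k_MR4p=376.0, k_MR5=108.0, k_MR5p=90.0e-3, k_MR6=2.03e3,
        k_EX=7.29,
    ),
    "ExGAP": KineticParameterSet(
        k_MR1=4.14e-3, k_MR2=0.589, k_MR2p=2.62, k_MR3=0.0262e3, k_MR3p=36.2,
        k_MR4=403.0, k_MR4p=16.4, k_MR5=0.0967, k_MR5p=106e-3, k_MR6=1.17e3,
        k_EX=3.47,
    ),
}

# reported standard deviations on the same scale (for identifiability context)
REFERENCE_STD: dict[str, dict[str, float]] = {
    "ExCARB": {
        "k_MR1": 0.02e-3, "k_MR2": 4.55, "k_MR2p": 1.41, "k_MR3": 7.21e3,
        "k_MR3p": 964.0, "k_MR4": 7.4, "k_MR4p": 0.01, "k_MR5": 0.470,
        "k_MR5p": 15e-3, "k_MR6": 1.38e3, "k_EX": 0.0040,
    },
}


def reference_parameters(calibration: str) -> KineticParameterSet:
    """Reference parameter estimates by calibration name.

    Calibration names are the variant ids plus ``w/oEx*`` (the no-excretion
    model re-calibrated on the full experiment, used for chemostat
    validation of the no-excretion hypothesis).
    """
    try:
        return REFERENCE_ESTIMATES[calibration]
    except KeyError:
        raise KeyError(
            f"unknown calibration {calibration!r}; "
            f"available: {', '.join(REFERENCE_ESTIMATES)}"
        ) from None
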