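"""Model-object front end tying the network, forcing and calibration together.

:class:`MacroKineticModel` is the main entry point: construct it from a
variant identifier (plus optional forcing), then ``simulate`` trajectories,
``fit`` it to a :class:`~drumalg.calibration.MeasurementSet` (returning a
results object with estimates, standard errors, AICc and a summary table), or
solve chemostat ``steady_state`` problems.
"""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationResult, MeasurementSet, fit_parameters, weighted_sse
from .chemostat import SteadyStateResult, run_chemostat_to_steady_state, sweep_dilution
from .forcing import ForcingProtocol
from .network import MacroReactionNetwork, build_variant
from .params import KineticParameterSet, reference_parameters
from .simulate import CultureState, Trajectory, simulate

__all__ = ["MacroKineticModel"]


class MacroKineticModel:
    """One model variant of the reduced *T. lutea* metabolism.

    Parameters
    ----------
    variant
        ``w/oEx``, ``ExCARB``, ``ExG6P``, ``ExPEP`` or ``ExGAP``.
    forcing
        Default forcing protocol for simulations (optional; operations that
        need one fall back to it when not passed explicitly).
    """

    def __init__(self, variant: str, forcing: ForcingProtocol | None = None):
        self.network: MacroReactionNetwork = build_variant(variant)
        self.forcing = forcing

    @property
    def variant(self) -> str:
        return self.network.variant.id

    def reference_parameters(self, calibration: str | None = None) -> KineticParameterSet:
        """Published-style reference estimates for this variant (or ``w/oEx*``)."""
        return reference_parameters(calibration or self.variant)

    # -- simulation -----------------------------------------------------------

    def simulate(
        self,
        params: KineticParameterSet,
        initial: CultureState,
        t_span: tuple[float, float],
        forcing: ForcingProtocol | None = None,
        **kwargs,
    ) -> Trajectory:
        forcing = forcing or self.forcing
        if forcing is None:
            raise ValueError("no forcing protocol given or set on the model")
        return simulate(self.network, params, forcing, initial, t_span, **kwargs)

    # -- calibration ----------------------------------------------------------

    def sse(self, params: KineticParameterSet, data: MeasurementSet, **kwargs) -> float:
        return weighted_sse(self.network, params, data, **kwargs)

    def fit(
        self,
        data: MeasurementSet,
        base_params: KineticParameterSet | None = None,
        **kwargs,
    ) -> CalibrationResult:
        """Multistart Nelder-Mead calibration; see :func:`drumalg.calibration.fit_parameters`."""
        base = base_params or self.reference_parameters()
        return fit_parameters(self.network, data, base, **kwargs)

    # -- chemostat ------------------------------------------------------------

    def steady_state(
        self, params: KineticParameterSet, dilution_per_day: float, **kwargs
    ) -> SteadyStateResult:
        return run_chemostat_to_steady_state(
            self.network, params, dilution_per_day, **kwargs
        )

    def dilution_sweep(
        self, params: KineticParameterSet, dilutions_per_day: np.ndarray, **kwargs
    ) -> list[SteadyStateResult]:
        return sweep_dilution(self.network, params, dilutions_per_day, **kwargs)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MacroKineticModel(variant={self.variant!r})"
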