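"""A-posteriori ATP / NADPH balance audit along a trajectory.

The macro-reaction model does not constrain energy cofactors; whether their
production and consumption roughly balance is a plausibility check computed
after simulation.  The audit operates at macro-reaction granularity: the net
cofactor balance is exact at this level, while the gross production and
consumption split differs from what a whole-network flux decomposition would
give, so unbalance percentages are order-of-magnitude diagnostics.

Sign convention: positive unbalance means excess production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DYNAMIC_SPECIES
from .simulate import Trajectory

__all__ = ["CofactorAudit", "cofactor_fluxes"]

_I_B = DYNAMIC_SPECIES.index("B")

#: auditable cofactors; ATP/ADP are netted as ATP, NAD(H) can be pooled in
_COFACTOR_SPECIES = {"ATP": "ATP", "NADPH": "NADPH", "NADH": "NADH"}


@dataclass
class CofactorAudit:
    """Production/consumption flux series of one cofactor (mol/L/h)."""

    cofactor: str
    times: np.ndarray
    production: np.ndarray
    consumption: np.ndarray

    @property
    def net(self) -> np.ndarray:
        return self.production - self.consumption

    @property
    def unbalance_pct(self) -> float:
        """Time-aggregated 100 x (production - consumption) / production."""
        prod = np.trapezoid(self.production, self.times)
        cons = np.trapezoid(self.consumption, self.times)
        if prod <= 0:
            return float("nan")
        return 100.0 * (prod - cons) / prod

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times,
            f"{self.cofactor}_production_mol_per_L_h": self.production,
            f"{self.cofactor}_consumption_mol_per_L_h": self.consumption,
        })


def cofactor_fluxes(
    trajectory: Trajectory, cofactor: str, pool_nadh: bool = False
) -> CofactorAudit:
    """Audit one cofactor ('ATP' or 'NADPH') along a trajectory.

    Per reaction j with signed cofactor stoichiometry s_j and specific rate
    alpha_j, production(t) = sum_j max(0, s_j alpha_j B) and consumption(t) =
    -sum_j min(0, s_j alpha_j B).  A reversible reaction running net backwards
    therefore contributes to the opposite series.  ``pool_nadh`` adds the NADH
    stoichiometry into the NADPH audit.
    """
    if cofactor not in ("ATP", "NADPH"):
        raise ValueError(f"unknown cofactor {cofactor!r}; audit supports ATP and NADPH")
    network = trajectory.network
    s = np.array([r.coefficient(_COFACTOR_SPECIES[cofactor]) for r in network.reactions])
    if cofactor == "NADPH" and pool_nadh:
        s = s + np.array([r.coefficient("NADH") for r in network.reactions])

    b = trajectory.states[:, _I_B]
    flux = trajectory.alphas * b[:, None] * s[None, :]  # (n_times, n_reactions)
    production = np.sum(np.maximum(flux, 0.0), axis=1)
    consumption = -np.sum(np.minimum(flux, 0.0), axis=1)
    return CofactorAudit(cofactor, trajectory.times.copy(), production, consumption)
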