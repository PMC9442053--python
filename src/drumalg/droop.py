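"""Droop quota growth law with a carbon-excretion add-on.

The Droop model expresses the specific growth rate of a phytoplankton cell as
a function of its internal quota q of the limiting nutrient (here nitrogen,
gN/gC):

    mu(q) = mu_bar (1 - Q0 / q)

with mu_bar the hypothetical infinite-quota growth rate and Q0 the minimum
quota for growth.  The add-on complements it with a specific excretion rate
that increases linearly with the C/N ratio 1/q,

    eta(q) = eta_bar Q0 / q,

maximal (eta_bar) at the minimum quota.  Net primary production is their sum,

    mu(q) + eta(q) = mu_bar [1 - (1 - eta_bar/mu_bar) Q0 / q].

Both mu and eta are in 1/d.  mu(q) is negative below Q0 as written; consumers
that need a rate clamp it at zero themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DroopParameters",
    "droop_mu",
    "droop_eta",
    "npp",
    "fit_droop",
    "DroopModel",
    "DroopResults",
]


@dataclass(frozen=True)
class DroopParameters:
    mu_bar: float  # growth rate at hypothetical infinite quota (1/d)
    Q0: float  # minimum quota (gN/gC)
    eta_bar: float | None = None  # maximum excretion rate (1/d), at q = Q0

    def __post_init__(self) -> None:
        if self.mu_bar <= 0:
            raise ValueError("mu_bar must be positive")
        if self.Q0 <= 0:
            raise ValueError("Q0 must be positive")
        if self.eta_bar is not None and self.eta_bar < 0:
            raise ValueError("eta_bar must be non-negative")


def _check_q(q):
    q = np.asarray(q, float)
    if np.any(q <= 0):
        raise ValueError("quota q must be positive")
    return q


def droop_mu(q, params: DroopParameters):
    """Droop growth rate mu(q) = mu_bar (1 - Q0/q); negative below Q0."""
    q = _check_q(q)
    return params.mu_bar * (1.0 - params.Q0 / q)


def droop_eta(q, params: DroopParameters):
    """Excretion rate eta(q) = eta_bar Q0 / q (requires eta_bar)."""
    q = _check_q(q)
    if params.eta_bar is None:
        raise ValueError("eta_bar is not set on these parameters")
    return params.eta_bar * params.Q0 / q


def npp(q, params: DroopParameters):
    """Net primary production mu(q) + eta(q), via the closed form."""
    q = _check_q(q)
    eta_bar = params.eta_bar or 0.0
    return params.mu_bar * (1.0 - (1.0 - eta_bar / params.mu_bar) * params.Q0 / q)


def fit_droop(table: pd.DataFrame, fit_eta: bool = False) -> "DroopResults":
    """Least-squares fit of the Droop law to a quota/rate table.

    ``table`` needs columns ``q`` (gN/gC) and ``mu`` (1/d), plus ``eta`` when
    ``fit_eta``.  mu is linear in (mu_bar, mu_bar*Q0) against 1/q, so the fit
    is an exact linear least-squares solve (error minimised in mu given q);
    eta = c/q is fitted the same way and eta_bar recovered as c/Q0.
    """
    q = _check_q(table["q"].to_numpy(float))
    mu = table["mu"].to_numpy(float)
    if len(q) < (3 if fit_eta else 2):
        raise ValueError("need at least as many rows as parameters")
    if np.ptp(q) == 0:
        raise ValueError("degenerate table: all quotas equal")
    X = np.column_stack([np.ones_like(q), 1.0 / q])
    coef, res_mu, *_ = np.linalg.lstsq(X, mu, rcond=None)
    mu_bar, slope = float(coef[0]), float(coef[1])
    if mu_bar <= 0:
        raise ValueError("fit produced non-positive mu_bar; data outside the Droop regime")
    q0 = -slope / mu_bar

    eta_bar = None
    eta_resid = 0.0
    if fit_eta:
        if "eta" not in table.columns:
            raise ValueError("fit_eta requires an 'eta' column")
        eta = table["eta"].to_numpy(float)
        c = float(np.sum(eta / q) / np.sum(1.0 / q ** 2))
        eta_bar = c / q0
        eta_resid = float(np.sum((eta - c / q) ** 2))

    params = DroopParameters(mu_bar=mu_bar, Q0=q0, eta_bar=eta_bar)
    mu_resid = float(np.sum((mu - droop_mu(q, params)) ** 2))
    return DroopResults(params=params, mu_residual=mu_resid, eta_residual=eta_resid, n_obs=len(q))


@dataclass
class DroopResults:
    """Fitted Droop(+excretion) parameters and residual sums of squares."""

    params: DroopParameters
    mu_residual: float
    eta_residual: float
    n_obs: int

    def predict_mu(self, q):
        return droop_mu(q, self.params)

    def predict_eta(self, q):
        return droop_eta(q, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Droop quota model fit",
            f"  n = {self.n_obs}",
            f"  mu_bar = {p.mu_bar:.4g} 1/d",
            f"  Q0     = {p.Q0:.4g} gN/gC",
        ]
        if p.eta_bar is not None:
            lines.append(f"  eta_bar = {p.eta_bar:.4g} 1/d")
        lines.append(f"  residual SS (mu): {self.mu_residual:.4g}")
        if p.eta_bar is not None:
            lines.append(f"  residual SS (eta): {self.eta_residual:.4g}")
        return "\n".join(lines)


class DroopModel:
    """Model object over a quota/rate table; ``fit()`` returns :class:`DroopResults`."""

    def __init__(self, table: pd.DataFrame, fit_eta: bool = False):
        self.table = table
        self.fit_eta = fit_eta

    @classmethod
    def from_steady_states(cls, quota_rate_table: pd.DataFrame, fit_eta: bool = False):
        """Build from a chemostat sweep export (columns q_gN_per_gC, mu_per_day, ...)."""
        table = pd.DataFrame({
            "q": quota_rate_table["q_gN_per_gC"],
            "mu": quota_rate_table["mu_per_day"],
        })
        if "eta_per_day" in quota_rate_table.columns:
            table["eta"] = quota_rate_table["eta_per_day"]
        return cls(table, fit_eta=fit_eta)

    def fit(self) -> DroopResults:
        return fit_droop(self.table, fit_eta=self.fit_eta)
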