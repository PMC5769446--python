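"""Family-cohort simulator and empirical FRR estimation.

Serves as the Monte Carlo oracle for both risk models: draw one risk value
per family (two-point or beta distributed), draw each member's disease status
independently given that risk, then estimate familial relative risks from the
simulated cohort and compare with the closed forms.

Conditioning is on *exactly* k affected among the non-index members — the
configuration the closed-form FRR_k describes.  Extra disease-free members
lower the empirical FRR, so oracle comparisons against FRR_k use families of
size k + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .continuous import BetaRiskModel
from .dichotomous import DichotomousRiskModel
from .errors import DomainError, UndefinedEstimateError

__all__ = ["FamilyCohort", "EmpiricalFrr", "simulate_cohort", "empirical_frr"]


@dataclass(frozen=True)
class FamilyCohort:
    """Simulated families sharing one risk value each.

    ``risks`` has one entry per family; ``affected`` is an (n_families,
    family_size) 0/1 array, exchangeable within each row given the risk.
    """

    risks: np.ndarray
    affected: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, float)
        affected = np.asarray(self.affected, np.int8)
        if affected.ndim != 2 or affected.shape[0] != risks.shape[0]:
            raise DomainError("affected must be (n_families, family_size)")
        if np.any((risks < 0.0) | (risks > 1.0)):
            raise DomainError("family risks must lie in [0, 1]")
        object.__setattr__(self, "risks", risks)
        object.__setattr__(self, "affected", affected)

    @property
    def n_families(self) -> int:
        return self.affected.shape[0]

    @property
    def family_size(self) -> int:
        return self.affected.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per family member."""
        n, size = self.affected.shape
        return pd.DataFrame(
            {
                "family_id": np.repeat(np.arange(n), size),
                "risk": np.repeat(self.risks, size),
                "member_index": np.tile(np.arange(size), n),
                "affected": self.affected.ravel(),
            }
        )


@dataclass(frozen=True)
class EmpiricalFrr:
    """An empirical FRR estimate with its delta-method standard error."""

    estimate: float
    se: float
    n_conditioning: int

    def within(self, target: float, n_se: float = 3.0) -> bool:
        return abs(self.estimate - target) <= n_se * self.se


def simulate_cohort(model, n_families: int, family_size: int, seed: int) -> FamilyCohort:
    """Draw a cohort: per-family risks from ``model``, then conditionally
    independent Bernoulli disease indicators for each member.

    The two-point model must carry absolute risks (use
    ``DichotomousRiskModel.with_mean_risk``); the beta model's P already *is*
    a probability.  A fixed seed reproduces the cohort exactly.
    """
    if n_families < 1:
        raise DomainError(f"n_families must be >= 1, got {n_families}")
    if family_size < 2:
        raise DomainError(f"family_size must be >= 2, got {family_size}")
    rng = np.random.default_rng(seed)
    if isinstance(model, BetaRiskModel):
        risks = rng.beta(model.alpha, model.beta, size=n_families)
    elif isinstance(model, DichotomousRiskModel):
        if model.p_l is None or model.p_h is None:
            raise DomainError(
                "two-point model needs absolute risks; pin them with "
                "with_mean_risk(mean_risk) before simulating"
            )
        high = rng.random(n_families) < model.q
        risks = np.where(high, model.p_h, model.p_l)
    else:
        raise TypeError(f"cannot simulate from {type(model).__name__}")
    affected = (rng.random((n_families, family_size)) < risks[:, None]).astype(np.int8)
    return FamilyCohort(risks=risks, affected=affected, seed=seed)


def empirical_frr(
    cohort: FamilyCohort, k_affected: int, index_member: int = 0
) -> EmpiricalFrr:
    """Estimate FRR_k from a cohort.

    One member per family (position ``index_member``) is the "index" person;
    families where exactly ``k_affected`` of the remaining members are
    affected form the conditioning set.  The estimate is the index disease
    frequency in that set divided by the overall index disease frequency,
    with a delta-method standard error for the ratio of the two proportions.
    """
    if not 1 <= k_affected <= cohort.family_size - 1:
        raise DomainError(
            f"k_affected must lie in [1, family_size-1], got {k_affected} "
            f"for family_size {cohort.family_size}"
        )
    affected = cohort.affected
    index = affected[:, index_member]
    others = np.delete(affected, index_member, axis=1)
    cond = others.sum(axis=1) == k_affected
    n1 = int(cond.sum())
    if n1 == 0:
        raise UndefinedEstimateError(
            f"no family has exactly {k_affected} affected conditioning members"
        )
    n = cohort.n_families
    p1 = float(index[cond].mean())
    p0 = float(index.mean())
    if p0 == 0.0 or p1 == 0.0:
        raise UndefinedEstimateError("no affected index members; FRR estimate undefined")
    est = p1 / p0
    # var(log ratio) ~ (1-p1)/(n1 p1) + (1-p0)/(n p0); the covariance term is
    # O(n1/n) smaller and conservative to drop
    se = est * np.sqrt((1.0 - p1) / (n1 * p1) + (1.0 - p0) / (n * p0))
    return EmpiricalFrr(estimate=est, se=float(se), n_conditioning=n1)
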