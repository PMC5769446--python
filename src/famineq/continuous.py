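"""Beta-distributed continuous model of family-level disease risk.

The family's probability of disease, P, is treated as a random variable on
[0, 1]: it varies between families, is shared within a family, and family
members are independent given P.  Conditioning on one affected relative gives

    FRR = E[P^2] / E[P]^2 = 1 + CV^2,

so the familial relative risk pins the coefficient of variation of the risk
distribution.  With P ~ Beta(alpha, beta),

    E[P]  = alpha / (alpha + beta),
    CV^2  = beta / (alpha (alpha + beta + 1)),

and the pair (lifetime risk, FRR) identifies (alpha, beta) in closed form.
A beta with mean m cannot exceed CV^2 = (1 - m)/m, so only FRR < 1/m is
attainable — the feasibility bound enforced by :func:`beta_from_mean_frr`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .errors import DegenerateError, DomainError, InfeasibleError

__all__ = ["BetaRiskModel", "beta_from_mean_frr", "frr_from_beta", "distribution_functions"]


@dataclass(frozen=True)
class BetaRiskModel:
    """Family-level risk distribution P ~ Beta(alpha, beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0 and np.isfinite(self.alpha)):
            raise DomainError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0.0 and np.isfinite(self.beta)):
            raise DomainError(f"beta must be positive and finite, got {self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def cv2(self) -> float:
        """Squared coefficient of variation, beta / (alpha (alpha + beta + 1))."""
        return self.beta / (self.alpha * (self.alpha + self.beta + 1.0))

    @property
    def frr(self) -> float:
        return 1.0 + self.cv2

    def distribution(self) -> stats.rv_continuous:
        """The scipy frozen Beta(alpha, beta) distribution."""
        return stats.beta(self.alpha, self.beta)


def beta_from_mean_frr(mean_risk: float, frr: float) -> BetaRiskModel:
    """Fit (alpha, beta) from the lifetime risk and the familial relative risk.

    Moment matching is closed-form: with m = mean_risk and CV^2 = frr - 1,

        s = (1 - m) / (m (frr - 1)) - 1,   alpha = m s,   beta = (1 - m) s.

    Raises :class:`InfeasibleError` when frr >= 1/m (no beta distribution with
    mean m has so large a CV) and :class:`DegenerateError` at frr = 1 (the
    homogeneous point mass, s -> infinity).
    """
    if not 0.0 < mean_risk < 1.0:
        raise DomainError(f"mean_risk must lie in (0, 1), got {mean_risk}")
    if frr < 1.0:
        raise DomainError(f"frr must be >= 1, got {frr}")
    if frr == 1.0:
        raise DegenerateError(
            "frr = 1 implies zero risk variation (a point mass); "
            "the beta parameters diverge"
        )
    if frr >= 1.0 / mean_risk:
        raise InfeasibleError(
            f"frr = {frr} is not attainable with mean risk {mean_risk}: a beta "
            f"distribution with that mean requires frr < 1/mean = {1.0 / mean_risk:.6g}"
        )
    s = (1.0 - mean_risk) / (mean_risk * (frr - 1.0)) - 1.0
    return BetaRiskModel(alpha=mean_risk * s, beta=(1.0 - mean_risk) * s)


def frr_from_beta(model: BetaRiskModel) -> float:
    """Familial relative risk 1 + CV^2 implied by the risk distribution."""
    return model.frr


def distribution_functions(
    model: BetaRiskModel,
) -> tuple[Callable[[np.ndarray], np.ndarray], ...]:
    """Return (pdf, cdf, quantile) callables for the fitted risk distribution."""
    dist = model.distribution()
    return dist.pdf, dist.cdf, dist.ppf


def _pdf_mass(model: BetaRiskModel) -> float:
    """Numerical integral of the density over [0, 1] (diagnostic; ~1)."""
    pdf = model.distribution().pdf
    val, _ = quad(pdf, 0.0, 1.0, limit=200)
    return val
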