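"""Lorenz curves, Gini indices and tail-share statistics of disease risk.

Borrowed from the economics of income inequality: sort the population by
ascending risk, and let L(x) be the expected share of all disease carried by
the fraction x at lowest risk.  Perfect equality gives the diagonal L(x) = x;
the Gini index is twice the area between the diagonal and the curve.  "Top
X%" statistics always derive from the same curve as 1 - L(1 - X).

Both supported risk distributions have tractable Lorenz curves:

* beta model — L(u) is the normalized partial first moment below the
  u-quantile, i.e. the regularized incomplete beta function with first shape
  alpha + 1 evaluated at the u-quantile;
* two-point model — piecewise linear with a single kink at x = 1 - q.

The Gini index is integrated in the quantile domain (u -> L(u)) because a
fitted beta frequently has alpha < 1, making the density unbounded at zero;
the two-point Gini has the exact form q(1 - q)(IRR - 1)/(q IRR + 1 - q).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import singledispatch

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import betainc, betaincinv

from .continuous import BetaRiskModel
from .dichotomous import DichotomousRiskModel
from .errors import DomainError

__all__ = [
    "LorenzCurve",
    "lorenz",
    "lorenz_curve",
    "gini",
    "top_share",
    "tail_mean_ratio",
    "tail_median_ratio",
]

DEFAULT_GRID_SIZE = 1001


@dataclass(frozen=True)
class LorenzCurve:
    """An evaluated Lorenz curve: ordered (population fraction, burden fraction) pairs."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x, y = np.asarray(self.x, float), np.asarray(self.y, float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise DomainError("LorenzCurve needs matching 1-D arrays of length >= 2")
        if x[0] != 0.0 or x[-1] != 1.0 or np.any(np.diff(x) <= 0):
            raise DomainError("population fractions must increase from 0 to 1")
        if np.any(np.diff(y) < -1e-12) or np.any(y - x > 1e-9):
            raise DomainError("burden fractions must be nondecreasing with L(x) <= x")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def trapezoid_gini(self) -> float:
        """Gini recomputed from the discrete curve by the trapezoid rule."""
        return 1.0 - 2.0 * float(np.trapezoid(self.y, self.x))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"population_fraction": self.x, "burden_fraction": self.y}
        )


# Lorenz evaluation ---------------------------------------------------------


@singledispatch
def lorenz(model, u):
    """Evaluate the Lorenz curve L(u) of ``model`` at population fraction(s) ``u``."""
    raise TypeError(f"no Lorenz curve defined for {type(model).__name__}")


@lorenz.register
def _(model: BetaRiskModel, u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    interior = (u > 0.0) & (u < 1.0)
    # partial first moment of Beta(a,b) below its u-quantile is the
    # regularized incomplete beta I_x(a+1, b) at x = Q(u)
    qx = betaincinv(model.alpha, model.beta, u[interior])
    out[interior] = betainc(model.alpha + 1.0, model.beta, qx)
    out[u <= 0.0] = 0.0
    out[u >= 1.0] = 1.0
    return out if out.shape else float(out)


@lorenz.register
def _(model: DichotomousRiskModel, u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    q, irr = model.q, model.irr
    mean_rel = q * irr + 1.0 - q  # mean of the relative-risk variable R in {1, irr}
    kink = 1.0 - q
    out = np.where(
        u <= kink,
        u / mean_rel,
        (kink + (u - kink) * irr) / mean_rel,
    )
    out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def lorenz_curve(model, grid_size: int = DEFAULT_GRID_SIZE) -> LorenzCurve:
    """Tabulate the Lorenz curve on a uniform grid of ``grid_size`` points."""
    if grid_size < 2:
        raise DomainError(f"grid_size must be >= 2, got {grid_size}")
    x = np.linspace(0.0, 1.0, grid_size)
    return LorenzCurve(x=x, y=np.asarray(lorenz(model, x), dtype=float))


# Quantiles -----------------------------------------------------------------


@singledispatch
def _quantile(model, u: float) -> float:
    raise TypeError(f"no quantile function defined for {type(model).__name__}")


@_quantile.register
def _(model: BetaRiskModel, u: float) -> float:
    return float(model.distribution().ppf(u))


@_quantile.register
def _(model: DichotomousRiskModel, u: float) -> float:
    # absolute risks if pinned, otherwise the relative values (1, irr);
    # every statistic built on quantiles here is a ratio, so scale cancels
    low, high = (1.0, model.irr) if model.p_l is None else (model.p_l, model.p_h)
    return low if u <= 1.0 - model.q else high


# Scalar inequality statistics ----------------------------------------------


def gini(model) -> float:
    """Gini index G = 2 * integral of (u - L(u)) over [0, 1].

    Zero iff risk is identical for every family; approaches one as the whole
    burden concentrates in a vanishing fraction of families.
    """
    if isinstance(model, DichotomousRiskModel):
        q, irr = model.q, model.irr
        return q * (1.0 - q) * (irr - 1.0) / (q * irr + 1.0 - q)
    val, _ = quad(lambda u: float(lorenz(model, u)), 0.0, 1.0, epsabs=1e-9, limit=400)
    return 1.0 - 2.0 * val


def top_share(model, fraction: float) -> float:
    """Share of expected cases carried by the ``fraction`` of families at highest risk."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return 1.0
    return 1.0 - float(lorenz(model, 1.0 - fraction))


def tail_mean_ratio(model, fraction: float) -> float:
    """Mean risk in the top ``fraction`` relative to the mean risk of everyone else.

    With S the top share, the ratio is (S/fraction) / ((1-S)/(1-fraction)).
    """
    if not 0.0 < fraction < 1.0:
        raise DomainError(f"fraction must lie in (0, 1), got {fraction}")
    s = top_share(model, fraction)
    return (s / fraction) / ((1.0 - s) / (1.0 - fraction))


def tail_median_ratio(model, fraction: float) -> float:
    """Median risk in the top ``fraction`` relative to the median of everyone else.

    Both medians come straight from the quantile function:
    Q(1 - fraction/2) / Q((1 - fraction)/2).  Degenerate models give 1.
    """
    if not 0.0 < fraction < 1.0:
        raise DomainError(f"fraction must lie in (0, 1), got {fraction}")
    if isinstance(model, DichotomousRiskModel) and model.is_degenerate:
        return 1.0
    hi = _quantile(model, 1.0 - fraction / 2.0)
    lo = _quantile(model, (1.0 - fraction) / 2.0)
    return hi / lo
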