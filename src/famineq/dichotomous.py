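"""Two-risk-group (dichotomous) model of familial disease risk.

The population is split into a high-risk group, of proportion ``q``, and a
low-risk group, of proportion ``1 - q``.  Everyone in the same family belongs
to the same group, the within-group disease probabilities are ``p_h`` and
``p_l``, and the individual relative risk is ``IRR = p_h / p_l``.

The familial relative risk (FRR) conditions on affected relatives.  With one
affected family member,

    FRR_1 = (q IRR^2 + 1 - q) / (q IRR + 1 - q)^2,

and with two affected members,

    FRR_2 = (q IRR^3 + 1 - q) / ((q IRR + 1 - q)(q IRR^2 + 1 - q)).

Both depend only on (IRR, q), never on the absolute risks.  Given published
(FRR_1, FRR_2) the pair of equations can be inverted numerically to recover
(IRR, q) — the central trick this module implements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit

from .errors import DegenerateError, DomainError, InfeasibleError

__all__ = [
    "DichotomousRiskModel",
    "FrrPair",
    "frr_one_affected",
    "frr_two_affected",
    "frr_k_affected",
    "frr_supremum",
    "solve_dichotomous",
    "absolute_risks",
    "forward_residuals",
]


@dataclass(frozen=True)
class DichotomousRiskModel:
    """A two-point risk distribution: proportion ``q`` at risk ``p_h = irr * p_l``.

    ``irr >= 1`` by convention (the larger-risk group is labelled "high");
    constructing a model with ``irr < 1`` swaps the groups automatically.
    Absolute risks are optional — the FRRs depend only on ``(irr, q)``.
    """

    q: float
    irr: float
    p_l: float | None = None
    p_h: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise DomainError(f"q must lie in (0, 1), got {self.q}")
        if self.irr <= 0.0 or not math.isfinite(self.irr):
            raise DomainError(f"irr must be positive and finite, got {self.irr}")
        if self.irr < 1.0:
            # normalize: relabel the groups so the "high" group has the larger risk
            object.__setattr__(self, "q", 1.0 - self.q)
            object.__setattr__(self, "irr", 1.0 / self.irr)
            pl, ph = self.p_l, self.p_h
            object.__setattr__(self, "p_l", ph)
            object.__setattr__(self, "p_h", pl)
        if (self.p_l is None) != (self.p_h is None):
            raise DomainError("p_l and p_h must be set together")
        if self.p_l is not None and self.p_h is not None:
            if not 0.0 < self.p_l < 1.0 or not 0.0 < self.p_h <= 1.0:
                raise DomainError("absolute risks must lie in (0, 1]")
            if not math.isclose(self.p_h, self.irr * self.p_l, rel_tol=1e-9):
                raise DomainError(
                    f"p_h={self.p_h} inconsistent with irr*p_l={self.irr * self.p_l}"
                )

    @property
    def mean_risk(self) -> float | None:
        """Marginal disease probability q*p_h + (1-q)*p_l, or None if risks unset."""
        if self.p_l is None or self.p_h is None:
            return None
        return self.q * self.p_h + (1.0 - self.q) * self.p_l

    def with_mean_risk(self, mean_risk: float) -> "DichotomousRiskModel":
        """Return a copy with absolute risks pinned so the marginal risk is ``mean_risk``."""
        p_l, p_h = absolute_risks(self, mean_risk)
        return DichotomousRiskModel(q=self.q, irr=self.irr, p_l=p_l, p_h=p_h)

    @property
    def is_degenerate(self) -> bool:
        return self.irr == 1.0


@dataclass(frozen=True)
class FrrPair:
    """Published familial relative risks given one and (optionally) two affected relatives."""

    frr1: float
    frr2: float | None = None

    def __post_init__(self) -> None:
        if self.frr1 < 1.0:
            raise DomainError(f"frr1 must be >= 1, got {self.frr1}")
        if self.frr2 is not None and self.frr2 < self.frr1:
            raise DomainError(
                f"frr2 ({self.frr2}) < frr1 ({self.frr1}): no two-point mixture "
                "produces a decreasing FRR sequence"
            )


def _check_irr_q(irr: float, q: float) -> None:
    if not 0.0 < q < 1.0:
        raise DomainError(f"q must lie in (0, 1), got {q}")
    if irr < 1.0:
        raise DomainError(f"irr must be >= 1, got {irr}")


def frr_one_affected(irr: float, q: float) -> float:
    """FRR given one affected family member, (q*irr**2 + 1 - q) / (q*irr + 1 - q)**2."""
    _check_irr_q(irr, q)
    return (q * irr**2 + 1.0 - q) / (q * irr + 1.0 - q) ** 2


def frr_two_affected(irr: float, q: float) -> float:
    """FRR given two affected family members."""
    _check_irr_q(irr, q)
    return (q * irr**3 + 1.0 - q) / ((q * irr + 1.0 - q) * (q * irr**2 + 1.0 - q))


def frr_k_affected(irr: float, q: float, k: int) -> float:
    """FRR given ``k`` affected family members.

    Generalizes the one- and two-affected formulas through the moment identity
    FRR_k = E[R^(k+1)] / (E[R^k] E[R]) for the two-point relative-risk variable
    R in {1, irr}:

        FRR_k = (q irr^(k+1) + 1 - q) / ((q irr + 1 - q)(q irr^k + 1 - q)).

    Nondecreasing in k, bounded above by 1/q, with large-k limit
    irr / (q*irr + 1 - q) (which itself approaches 1/q only as irr grows).
    """
    _check_irr_q(irr, q)
    if int(k) != k or k < 1:
        raise DomainError(f"k must be an integer >= 1, got {k}")
    return (q * irr ** (k + 1) + 1.0 - q) / (
        (q * irr + 1.0 - q) * (q * irr**k + 1.0 - q)
    )


def frr_supremum(q: float) -> float:
    """Least upper bound 1/q of FRR_1 and FRR_2 over all irr >= 1.

    With a common high-risk group (large q) the FRR is structurally capped:
    at q = 0.8 no IRR, however extreme, pushes the FRR above 1.25.
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"q must lie in (0, 1), got {q}")
    return 1.0 / q


def absolute_risks(model: DichotomousRiskModel, mean_risk: float) -> tuple[float, float]:
    """Invert the marginal risk: (p_l, p_h) with q*p_h + (1-q)*p_l = mean_risk.

    Closed form: p_l = mean_risk / (q*irr + 1 - q), p_h = irr * p_l.
    """
    if not 0.0 < mean_risk < 1.0:
        raise DomainError(f"mean_risk must lie in (0, 1), got {mean_risk}")
    p_l = mean_risk / (model.q * model.irr + 1.0 - model.q)
    p_h = model.irr * p_l
    if p_h > 1.0:
        raise InfeasibleError(
            f"irr={model.irr} and mean_risk={mean_risk} imply p_h={p_h:.4g} > 1"
        )
    return p_l, p_h


def forward_residuals(model: DichotomousRiskModel, pair: FrrPair) -> tuple[float, float | None]:
    """Relative residuals (FRR_model/FRR_target - 1) of a forward check against ``pair``."""
    r1 = frr_one_affected(model.irr, model.q) / pair.frr1 - 1.0
    r2 = None
    if pair.frr2 is not None:
        r2 = frr_two_affected(model.irr, model.q) / pair.frr2 - 1.0
    return r1, r2


# Inverse solve -------------------------------------------------------------


def _irr_matching_frr1(f1: float, q: float) -> float:
    """The unique irr >= 1 with FRR_1(irr, q) = f1 (FRR_1 is strictly
    increasing in irr, from 1 toward 1/q).  Requires f1 < 1/q."""
    lo, hi = 1.0, 2.0
    while frr_one_affected(hi, q) < f1:
        hi *= 4.0
        if hi > 1e15:  # pragma: no cover - only reachable with f1 ~ 1/q
            break
    return optimize.brentq(
        lambda r: frr_one_affected(r, q) - f1, lo, hi, xtol=1e-14, rtol=1e-15
    )


def solve_dichotomous(pair: FrrPair) -> DichotomousRiskModel:
    """Recover (irr, q) from an (FRR_1, FRR_2) pair.

    Any pair with frr2 > frr1 > 1 is attainable by exactly one two-point
    mixture.  The 2-D system is stiff when q is small, so it is solved as
    nested 1-D bisections: for each candidate q < 1/frr1 the inner bracket
    pins irr from FRR_1 (strictly increasing in irr), and the outer bracket
    solves FRR_2(irr(q), q) = frr2 in q.  The outer function runs from
    +infinity (q -> 0, where irr -> infinity) down to frr1 (q -> 1/frr1), so
    a sign change is guaranteed and bisection cannot escape the domain.
    Forward residuals are verified to 1e-8 relative before returning.

    Raises
    ------
    DegenerateError
        When frr1 = frr2 = 1 (homogeneous population: irr = 1, q unidentifiable).
    InfeasibleError
        When frr1 <= 1 or frr2 <= frr1 (no interior two-point mixture), or the
        iteration cannot reach relative residuals <= 1e-8.
    """
    if pair.frr2 is None:
        raise DomainError("solve_dichotomous needs both frr1 and frr2")
    f1, f2 = pair.frr1, pair.frr2
    if f1 == 1.0 and f2 == 1.0:
        raise DegenerateError(
            "frr1 = frr2 = 1: homogeneous population, irr = 1 with q unidentifiable"
        )
    if f1 <= 1.0:
        raise InfeasibleError(f"frr1 must exceed 1 for an interior solution, got {f1}")
    if f2 <= f1:
        raise InfeasibleError(
            f"frr2 ({f2}) must strictly exceed frr1 ({f1}) for a two-point mixture"
        )

    q_max = 1.0 / f1  # FRR_1 < 1/q forces q < 1/frr1

    def outer(logit_q: float) -> float:
        q = float(expit(logit_q)) * q_max
        if q >= q_max * (1.0 - 1e-9):
            return f1 - f2  # analytic limit: irr -> infinity, FRR_2 -> 1/q = frr1
        irr = _irr_matching_frr1(f1, q)
        return frr_two_affected(irr, q) - f2

    # bracket the outer root on the logit scale; outer(-inf) = +inf,
    # outer(+inf) = f1 - f2 < 0
    lo, hi = -40.0, 36.0
    grid = np.linspace(lo, hi, 120)
    vals = [outer(t) for t in grid]
    idx = next((i for i in range(len(grid) - 1) if vals[i] > 0.0 >= vals[i + 1]), None)
    if idx is None:
        raise InfeasibleError(f"no (irr, q) attains (frr1={f1}, frr2={f2})")
    t = optimize.brentq(outer, grid[idx], grid[idx + 1], xtol=1e-14, rtol=1e-15)
    q = float(expit(t)) * q_max
    irr = _irr_matching_frr1(f1, q)
    r1 = frr_one_affected(irr, q) / f1 - 1.0
    r2 = frr_two_affected(irr, q) / f2 - 1.0
    if max(abs(r1), abs(r2)) > 1e-8:
        raise InfeasibleError(
            f"no (irr, q) attains (frr1={f1}, frr2={f2}); best residuals "
            f"({r1:.2e}, {r2:.2e})"
        )
    return DichotomousRiskModel(q=q, irr=irr)
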