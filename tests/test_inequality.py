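"""Lorenz curves, Gini indices and tail statistics, against closed-form oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import betaln

from famineq import (
    BetaRiskModel,
    DichotomousRiskModel,
    DomainError,
    beta_from_mean_frr,
    gini,
    lorenz,
    lorenz_curve,
    tail_mean_ratio,
    tail_median_ratio,
    top_share,
)


def beta_gini_closed_form(model: BetaRiskModel) -> float:
    """Independent oracle: G = 2 B(2a, 2b) / (a B(a, b)^2)."""
    a, b = model.alpha, model.beta
    return 2.0 * np.exp(betaln(2 * a, 2 * b) - 2.0 * betaln(a, b)) / a


def test_uniform_lorenz_is_u_squared():
    u = np.linspace(0.0, 1.0, 101)
    assert np.allclose(lorenz(BetaRiskModel(1.0, 1.0), u), u**2, atol=1e-12)


def test_uniform_gini_is_one_third():
    assert gini(BetaRiskModel(1.0, 1.0)) == pytest.approx(1.0 / 3.0, abs=1e-9)
    assert beta_gini_closed_form(BetaRiskModel(1.0, 1.0)) == pytest.approx(1.0 / 3.0, rel=1e-12)


@pytest.mark.parametrize(
    "mean, frr",
    [(0.01, 2.3), (0.01, 1.5), (0.01, 6.0), (0.12, 1.8), (0.3, 2.24), (0.002, 12.0)],
)
def test_quadrature_gini_matches_closed_form(mean, frr):
    model = beta_from_mean_frr(mean, frr)
    assert gini(model) == pytest.approx(beta_gini_closed_form(model), abs=1e-6)


@pytest.mark.parametrize(
    "model",
    [
        beta_from_mean_frr(0.01, 2.3),
        beta_from_mean_frr(0.002, 12.0),
        DichotomousRiskModel(q=0.10, irr=5.2),
    ],
    ids=["beta-parkinson", "beta-t1d", "two-point"],
)
def test_lorenz_curve_invariants(model):
    curve = lorenz_curve(model, grid_size=10_001)
    y = curve.y
    assert y[0] == 0.0 and y[-1] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(y) >= -1e-12)
    assert np.all(y <= curve.x + 1e-9)
    # discrete convexity: successive increments nondecreasing
    assert np.all(np.diff(y, 2) >= -1e-9)


def test_trapezoid_gini_consistent_with_quadrature():
    model = beta_from_mean_frr(0.01, 2.3)
    curve = lorenz_curve(model, grid_size=10_001)
    assert curve.trapezoid_gini() == pytest.approx(gini(model), abs=1e-4)


def test_two_point_gini_matches_trapezoid():
    model = DichotomousRiskModel(q=0.10, irr=5.2)
    curve = lorenz_curve(model, grid_size=100_001)
    assert curve.trapezoid_gini() == pytest.approx(gini(model), abs=1e-4)


def test_two_point_lorenz_shapes():
    # equal risks: the diagonal
    eq = DichotomousRiskModel(q=0.3, irr=1.0)
    u = np.linspace(0.0, 1.0, 11)
    assert np.allclose(lorenz(eq, u), u, atol=1e-14)
    assert gini(eq) == 0.0
    # heterogeneous: single kink at 1-q, linear on either side
    m = DichotomousRiskModel(q=0.2, irr=4.0)
    left = np.linspace(0.0, 0.8, 9)
    right = np.linspace(0.8, 1.0, 9)
    assert np.allclose(np.diff(lorenz(m, left), 2), 0.0, atol=1e-12)
    assert np.allclose(np.diff(lorenz(m, right), 2), 0.0, atol=1e-12)


@pytest.mark.parametrize(
    "mean, frr, fraction, expected",
    [
        # the 10% at highest risk account for 26% of diagnoses at FRR 1.5 ...
        (0.01, 1.5, 0.10, 0.26),
        # ... and 65% at FRR 6
        (0.01, 6.0, 0.10, 0.65),
        (0.12, 1.8, 0.10, 0.30),
        # type 1 diabetes: a quarter of cases in 1% of families
        (0.002, 12.0, 0.01, 0.25),
    ],
)
def test_top_shares_match_published_values(mean, frr, fraction, expected):
    assert top_share(beta_from_mean_frr(mean, frr), fraction) == pytest.approx(
        expected, abs=0.01
    )


def test_top_share_trivia():
    model = beta_from_mean_frr(0.01, 2.3)
    assert top_share(model, 1.0) == 1.0
    assert top_share(model, 0.10) > 0.10  # heterogeneity concentrates burden
    with pytest.raises(DomainError):
        top_share(model, 0.0)


def test_tail_mean_ratio_uniform_and_degenerate():
    assert tail_mean_ratio(BetaRiskModel(1.0, 1.0), 0.5) == pytest.approx(3.0, abs=1e-9)
    assert tail_mean_ratio(DichotomousRiskModel(q=0.2, irr=1.0), 0.10) == pytest.approx(1.0)


def test_tail_mean_ratio_brute_force_oracle():
    # conditional means integrated directly from the density
    model = beta_from_mean_frr(0.12, 1.8)
    frac = 0.10
    pdf, _, ppf = model.distribution().pdf, model.distribution().cdf, model.distribution().ppf
    cut = float(ppf(1.0 - frac))
    num_hi, _ = quad(lambda p: p * pdf(p), cut, 1.0, limit=400)
    num_lo, _ = quad(lambda p: p * pdf(p), 0.0, cut, limit=400)
    oracle = (num_hi / frac) / (num_lo / (1.0 - frac))
    assert tail_mean_ratio(model, frac) == pytest.approx(oracle, rel=1e-6)


def test_tail_median_ratio_uniform_and_degenerate():
    assert tail_median_ratio(BetaRiskModel(1.0, 1.0), 0.5) == pytest.approx(3.0, rel=1e-12)
    assert tail_median_ratio(DichotomousRiskModel(q=0.2, irr=1.0), 0.10) == 1.0


def test_monotone_in_frr_at_fixed_mean():
    models = [beta_from_mean_frr(0.01, f) for f in (1.5, 2.3, 6.0)]
    ginis = [gini(m) for m in models]
    shares = [top_share(m, 0.10) for m in models]
    assert ginis[0] < ginis[1] < ginis[2]
    assert shares[0] < shares[1] < shares[2]


def test_monte_carlo_gini_oracle():
    # sample Gini of 10^6 beta draws vs the quadrature Gini, within 3 SE
    model = beta_from_mean_frr(0.01, 2.3)
    rng = np.random.default_rng(7)
    p = np.sort(rng.beta(model.alpha, model.beta, size=1_000_000))
    n = p.size
    i = np.arange(1, n + 1)
    sample_gini = 2.0 * np.sum(i * p) / (n * np.sum(p)) - (n + 1.0) / n
    # block-based standard error (100 blocks of 10^4)
    blocks = p.copy()
    rng.shuffle(blocks)
    bg = []
    for b in blocks.reshape(100, -1):
        b = np.sort(b)
        m = b.size
        j = np.arange(1, m + 1)
        bg.append(2.0 * np.sum(j * b) / (m * np.sum(b)) - (m + 1.0) / m)
    se = np.std(bg) / 10.0
    assert abs(sample_gini - gini(model)) <= 3.0 * se + 1e-4


def test_lorenz_curve_csv_roundtrip(tmp_path):
    curve = lorenz_curve(beta_from_mean_frr(0.01, 2.3), grid_size=101)
    path = tmp_path / "lorenz.csv"
    curve.to_frame().to_csv(path, index=False, float_format="%.17g")
    back = np.loadtxt(path, delimiter=",", skiprows=1)
    assert np.allclose(back[:, 0], curve.x) and np.allclose(back[:, 1], curve.y)
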