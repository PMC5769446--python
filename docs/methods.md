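# Methods

## Models and assumptions

famineq treats disease risk as a family-level quantity: every member of a
family shares one probability of developing the disease over a fixed horizon
(a lifetime risk, or risk by a given age), members are independent given
that probability, and the probability varies between families. Familial
relationship degree, ascertainment, age at onset and time-to-event structure
are all outside the models; the familial relative risk (FRR) is a fixed-
horizon probability ratio, not a hazard ratio.

**Two-group model.** The family-level risk takes two values: a fraction `q`
of families is "high-risk" with per-member probability `p_h = irr * p_l`.
The FRR given `k` affected members follows from the moment identity
`FRR_k = E[R^(k+1)] / (E[R^k] E[R])` for the two-point relative-risk
variable `R ∈ {1, irr}`:

    FRR_k = (q irr^(k+1) + 1 - q) / ((q irr + 1 - q)(q irr^k + 1 - q)).

Two structural facts drive every result downstream: `FRR_k < 1/q` for any
finite `irr` (a common high-risk group caps the FRR), and as `k` grows
`FRR_k → irr / (q irr + 1 - q)` — conditioning on many affected members
identifies the high-risk group, so the FRR tends to the high-group risk over
the population mean, approaching `1/q` only in the `irr → ∞` limit.

`irr >= 1` is a labelling convention; a model constructed with `irr < 1`
swaps the groups. Absolute risks are optional because FRRs depend only on
`(irr, q)`; they are pinned from a marginal risk `m` via
`p_l = m / (q irr + 1 - q)` when the simulator needs them. Note that
infeasibility (`p_h > 1`) requires `m/q > 1` *and* a large `irr` — the bound
is `p_h < m/q`, so common diseases with large `q` can absorb any `irr`.

**Continuous model.** The family-level risk is `P ~ Beta(α, β)`, and
`FRR = E[P²]/E[P]² = 1 + CV²`. Moment matching from `(E[P], FRR)` is closed
form: `s = (1-m)/(m(FRR-1)) - 1`, `α = m s`, `β = (1-m) s`. The fit is
rejected when `FRR >= 1/m` (no beta with mean `m` attains that CV²) and at
`FRR = 1` exactly (a point mass; the shapes diverge — callers wanting a
homogeneous population should use the two-group model with `irr = 1`).
Fitted shapes very often have `α < 1`, i.e. a density unbounded at zero;
nothing downstream assumes a bounded density.

The continuous model consumes FRR₁ (one affected relative); FRR₂ is used
only by the two-group inverse solve, whose identifiability needs two
equations.

## Inverse solve of the two-group model

Given `(frr1, frr2)` with `frr2 > frr1 > 1`, exactly one `(irr, q)` in
`(1, ∞) × (0, 1)` reproduces the pair. The 2-D system is stiff when `q` is
small, and Newton-type iterations stall when `frr2 - frr1` is small (the
solution then sits near the `q = 1/frr1` boundary where `irr` diverges).
The solver therefore nests two bisections, each with a guaranteed bracket:

1. `FRR_1` is strictly increasing in `irr` at fixed `q` (derivative
   `2 q (1-q)(irr-1) / (q irr + 1 - q)^3 > 0`), so the inner `brentq` pins
   `irr(q)` from `frr1` for any `q < 1/frr1`.
2. The outer function `g(q) = FRR_2(irr(q), q) - frr2` runs from `+∞` as
   `q → 0` (there `irr(q) → ∞` and `FRR_2 → irr`) down to `frr1 - frr2 < 0`
   as `q → 1/frr1`; the outer `brentq` works on a logit-rescaled `q` with
   the boundary clamped to its analytic limit.

Both bisections run at `xtol = 1e-14`; the returned model is forward-checked
to relative residuals ≤ 1e-8 (in practice ~1e-15). Degenerate input
`frr1 = frr2 = 1` raises rather than returning an arbitrary `q`; pairs with
`frr2 <= frr1` are rejected up front since no two-point mixture produces a
non-increasing FRR sequence. Published tables round their values, so forward
residuals of *printed* `(IRR, q)` against printed FRRs need not vanish; the
catalog reports residuals for exactly this reason.

## Lorenz curves, Gini and tail statistics

Families are sorted by ascending risk; `L(u)` is the share of expected cases
in the lowest-risk fraction `u`. For the beta model `L(u)` is the normalized
partial first moment below the `u`-quantile, computed as the regularized
incomplete beta function with first shape `α + 1` evaluated at the
`u`-quantile — no sampling and no density integration, which matters because
`α < 1` makes the density singular at zero. For the two-point model `L` is
piecewise linear with one kink at `1 - q`.

The Gini index is `G = 2∫(u - L(u))du`, integrated in the quantile domain by
adaptive quadrature (absolute tolerance 1e-9, limit 400); the two-point case
uses the exact form `q(1-q)(irr-1)/(q irr + 1 - q)`. The analytic beta Gini
`2 B(2α, 2β) / (α B(α, β)²)` is kept out of the implementation and used as
an independent oracle in the tests (validated first on Beta(1,1) → 1/3).

Top-share statistics always derive from the curve as `1 - L(1 - f)`, never
from re-sorting samples. The tail mean ratio is
`(S/f) / ((1-S)/(1-f))` with `S` the top share; the tail *median* ratio uses
the quantile function exactly: `Q(1 - f/2) / Q((1 - f)/2)`. Emitted curves
default to 1001 uniformly spaced points; CSV export keeps full double
precision.

Known limitation: for breast cancer (mean 0.12, FRR 1.8) the top-10% mean
ratio under the conditional-mean definition above is ≈ 3.85, and for type 1
diabetes (mean 0.002, FRR 12) the top-1% median ratio is ≈ 8950. Other
published summaries of the same scenarios quote larger ratios (6.2 and
"more than 10,000"); those figures are not reproducible under these
definitions — e.g. the *mean* of the top 1% over the *median* of the rest is
≈ 1.0 × 10⁴ — so the definitions used here are stated exactly and the
computed values stand.

## Simulator

`simulate_cohort` draws one risk per family (two-point or beta) and then
i.i.d. Bernoulli indicators per member, from a single `numpy` Generator with
an explicit integer seed; there is no global random state, and equal seeds
reproduce cohorts bit for bit.

`empirical_frr` designates member 0 as the index person (exchangeability
makes the choice immaterial; a test permutes it) and conditions on *exactly*
`k` affected among the other members — the configuration the closed forms
describe. Consequently the oracle comparisons against `FRR_k` use families
of size `k + 1`: an additional disease-free member is genuine evidence of
lower risk and pulls the empirical FRR below the `k + 1`-member closed form
(the size-3, `k = 1` estimate for the testicular-cancer scenario sits at
≈ 5.3 against a two-member value of 6.16 — a feature, not an estimator
defect). The standard error is delta-method on the ratio of the two
proportions, dropping the `O(n₁/n)` covariance term (conservative).

Simulation checks in the tests use 10⁶ families with 3-standard-error
acceptance bands; sample-Gini standard errors come from 100 blocks of 10⁴
sorted draws. These sizes keep the whole suite in a few seconds while
leaving Monte Carlo error an order of magnitude below every effect tested.

## What the simulator does and does not emulate

It emulates exactly the generative assumptions of the two models — shared
within-family risk, conditional independence, exchangeable members — so
agreement between empirical and closed-form FRRs validates the algebra and
the estimator, not the models' realism. Real family data add relationship
structure (siblings vs parents), ascertainment bias, age effects and
within-family risk heterogeneity, none of which are generated or corrected
for; passing tests say nothing about those.

## Catalog driver

The packaged catalog (`src/famineq/data/diseases.csv`) carries published
FRR estimates for seven cancers with (FRR₁, FRR₂) pairs and six diseases
with lifetime risks. Catalog risks are proportions (0.12, not 12%); values
above 1 are rejected with a hint rather than silently rescaled. Each row is
processed independently — an infeasible row yields a per-row warning, never
a batch abort — and rendering is deterministic byte for byte: text rounds to
3 significant figures and omits the warnings column when empty; CSV and JSON
keep full precision.
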