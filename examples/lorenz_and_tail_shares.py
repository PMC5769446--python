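"""Lorenz curve and tail-share statistics for a fitted risk distribution.

With a 1% lifetime risk, compare a modest FRR of 1.5 with a strong FRR of 6:
how much of the disease burden falls on the 10% of families at highest risk?
"""

from famineq import beta_from_mean_frr, gini, lorenz_curve, tail_median_ratio, top_share

for frr in (1.5, 6.0):
    model = beta_from_mean_frr(mean_risk=0.01, frr=frr)
    print(f"FRR {frr:>3}: Gini {gini(model):.3f}, "
          f"top-10% share {100 * top_share(model, 0.10):.1f}%")

# type 1 diabetes: rare (0.2%) but strongly familial (FRR 12)
t1d = beta_from_mean_frr(mean_risk=0.002, frr=12.0)
print(f"T1D: top-1% share {100 * top_share(t1d, 0.01):.1f}%, "
      f"top-1% / rest median risk ratio {tail_median_ratio(t1d, 0.01):.0f}")

curve = lorenz_curve(t1d, grid_size=11)
for x, y in curve.points:
    print(f"  L({x:.1f}) = {y:.4f}")
# The curve hugs zero until the very top: nearly the whole burden sits in the
# most at-risk sliver of families.
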