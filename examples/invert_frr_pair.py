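"""Invert a published (FRR1, FRR2) pair for the hidden two-group risk structure.

Breast cancer in female first-degree relatives: the risk roughly doubles with
one affected relative (FRR1 = 1.80) and triples with two (FRR2 = 2.93).  The
two-group model asks: what size of high-risk group, at what relative risk,
would produce exactly those numbers?
"""

from famineq import FrrPair, forward_residuals, solve_dichotomous

pair = FrrPair(frr1=1.80, frr2=2.93)
model = solve_dichotomous(pair)
r1, r2 = forward_residuals(model, pair)

print(f"IRR (high vs low group risk ratio): {model.irr:.3f}")
print(f"q (high-risk share of population):  {model.q:.4f}")
print(f"forward residuals: {r1:.2e}, {r2:.2e}")
# A modest doubling of familial risk hides a 10% subgroup whose members are
# more than five times as likely to develop the disease as everyone else.
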