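"""Fit the continuous (beta) risk distribution from lifetime risk and FRR.

Parkinson's disease: lifetime risk about 1%, familial relative risk 2.3.
The FRR fixes the squared coefficient of variation of the family-level risk
(FRR = 1 + CV^2), and together with the mean that pins the beta shape.
"""

from famineq import beta_from_mean_frr, frr_from_beta, gini

model = beta_from_mean_frr(mean_risk=0.01, frr=2.3)
print(f"alpha = {model.alpha:.3f}, beta = {model.beta:.1f}")
print(f"implied FRR (roundtrip): {frr_from_beta(model):.2f}")
print(f"Gini index of risk: {gini(model):.3f}")
# A Gini of 0.55 means disease risk is spread *less* equally across families
# than income is across US households (Gini 0.45).
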