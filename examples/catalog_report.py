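"""Run both models over the packaged disease catalog and print the summary.

Each row with an (FRR1, FRR2) pair gets the two-group inverse solution
(IRR, q); each row with a lifetime risk gets the beta fit with its Gini index
and top-10% / top-1% case shares.
"""

from famineq import example_catalog, render_report, run_catalog

reports = run_catalog(example_catalog())
print(render_report(reports, format="text"))
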