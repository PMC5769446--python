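name,relationship,frr1,frr2,lifetime_risk
Testicular cancer,brothers,5.88,21.71,0.009
Prostate cancer,brothers,2.96,7.71,
Colorectal cancer,siblings,2.25,4.25,
Melanoma,first-degree relatives,1.9,4.7,
Breast cancer,female first-degree relatives,1.80,2.93,0.12
Hodgkin lymphoma,first-degree relatives,6,13,
Non-medullary thyroid cancer,first-degree relatives,3.1,23.2,
Parkinson disease,first-degree relatives,2.3,,0.01
Pancreatic cancer,first-degree relatives,2.19,,0.015
Leukemias,first-degree relatives,2.01,,0.0096
Stomach cancer,first-degree relatives,1.92,,0.0178
Diabetes type 2,first-degree relatives,2.24,,0.30
Diabetes type 1,siblings,12,,0.002
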