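"""Grade classification and responsible-vector identification.

A logistic regression on standardized codeword counts predicts the binary
grade (HGG-like positive). Codewords that are significantly associated
with grade — marginal effect likelihood-ratio test gated by a rank-sum
comparison of the per-class count distributions — are the grade's
"responsible vectors". This runs the full desk-scale study for one seed.
"""

from vqradiomics.experiment import run_phantom_experiment

res = run_phantom_experiment(seed=1, epochs=8)

print("5-fold CV:", res.cv_report.summary())
print("HGG-responsible codewords:", res.responsible.hgg_responsible)
print("LGG-responsible codewords:", res.responsible.lgg_responsible)
print(res.responsible.records.to_string(index=False))
# HGG-responsible codewords have higher mean counts in HGG-like volumes
# (they encode the bright, enhancing core and its surroundings); the
# LGG-responsible codewords mirror this for the dark core.
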