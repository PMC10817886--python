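"""Fit the three randomized classifiers on a synthetic feature cloud.

Generates a separable two-class Gaussian set, fits ELM / RVFLN / deep RVFL
in closed form, and prints training accuracy and the design-matrix width of
each.  The deep RVFL's width is the sum of its layer widths plus the input
dimension (its output layer sees everything).
"""

import numpy as np

import rvflkit as rk

fm = rk.gen_features(rk.FeatureSimConfig(n_per_class=500, dim=24,
                                         separation=4.0, seed=1))

models = {
    "elm (h=100)": rk.fit_elm(fm, h=100, seed=2),
    "rvfln (h=100)": rk.fit_rvfln(fm, h=100, seed=2),
    "drvfl [12,12,12]": rk.fit_drvfl(fm, [12, 12, 12], seed=2),
}
for name, model in models.items():
    pred = rk.predict(model, fm)
    acc = np.mean([a == b for a, b in zip(pred.labels, fm.labels)])
    print(f"{name:18s} design width {model.alpha.shape[0]:4d}  "
          f"training accuracy {acc:.3f}")
# Training accuracy near 1.0 is expected: the class means sit 4 within-class
# standard deviations apart in every one of the 24 features.
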