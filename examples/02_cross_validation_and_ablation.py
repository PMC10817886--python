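"""Stratified five-fold evaluation and a width ablation.

Cross-validates a deep RVFL, then sweeps the per-layer width over the
standard ablation grid {6, 12, 18, 24} (three equal layers each) and prints
the mean±std six-metric table.
"""

import rvflkit as rk
from rvflkit.evaluation import METRIC_COLUMNS, ablate

fm = rk.gen_features(rk.FeatureSimConfig(n_per_class=500, dim=24,
                                         separation=4.0, seed=3))

report = rk.cross_validate(
    fm, rk.ClassifierSpec(kind="drvfl", widths=(12, 12, 12)), k=5, seed=4)
print("5-fold CV, drvfl [12,12,12]:")
for m in METRIC_COLUMNS:
    s = report["summary"][m]
    print(f"  {m:12s} {s['mean']:.4f} ± {s['std']:.4f}")

table = ablate(fm, "drvfl", k=5, seed=4)  # default grid 6/12/18/24
print("\nAblation (accuracy mean±std per width):")
for _, row in table.iterrows():
    print(f"  width {int(row['width']):3d}: "
          f"{row['accuracy_mean']:.4f} ± {row['accuracy_std']:.4f}")
# On this separable benchmark every width saturates near 1.0; on real deep
# features the sweep is what identifies the best architecture.
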