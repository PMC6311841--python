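"""Derive report metrics from raw confusion counts.

Takes a confusion table (positive class = malignant) and prints the five
derived metrics, raw and at 2-decimal report rounding.
"""

from sonodae import ConfusionCounts
from sonodae.metrics import metric_suite, rounded_suite

counts = ConfusionCounts(TP=18, TN=15, FP=5, FN=2)
raw = metric_suite(counts)
rounded = rounded_suite(counts)

print(f"counts: TP={counts.TP} TN={counts.TN} FP={counts.FP} FN={counts.FN} (n={counts.total})")
for name in ("precision", "recall", "specificity", "accuracy", "f_measure"):
    print(f"{name:<12} {raw[name]:.4f}  (report: {rounded[name]:.2f})")
# With 40 test images and 7 errors, accuracy 33/40 = 0.825 rounds to 0.83
# under half-away-from-zero report rounding.
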