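"""Recompute the published 4-class scores from the printed confusion matrix.

The matrix (rows = predicted, columns = actual; classes N, SAH, IPH, ASDH) is
a published result; feeding it through the metric suite reproduces the
printed per-class F1 scores and the overall micro-averaged F1.
"""

import numpy as np

from hemoct.metrics import ConfusionMatrix, per_class_metrics

labels = ("N", "SAH", "IPH", "ASDH")
counts = np.array(
    [
        [129, 30, 4, 0],
        [7, 100, 35, 3],
        [15, 31, 32, 0],
        [1, 7, 1, 29],
    ]
)

report = per_class_metrics(ConfusionMatrix(counts, labels))
for label in labels:
    m = report.per_class[label]
    print(f"{label:4s} sensitivity={m.sensitivity:.3f} precision={m.precision:.3f} F1={m.f1:.3f}")
print(f"overall (micro) F1 = {report.micro_f1:.3f}")  # 290 correct of 424
print(f"macro F1           = {report.macro_f1:.3f}")
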