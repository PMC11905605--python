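"""Agreement metrics between NPA masks, with the undefined-value convention.

When a method detects no nonperfusion at all, precision has no denominator;
it is reported as UNDEFINED and dropped from aggregate means (so aggregate
rows can have different effective n).
"""

import numpy as np

from npabench import NPAMask, aggregate_metrics, agreement_metrics, confusion_counts
from npabench.types import PIXEL_PITCH_MM, disk_mask

shape = (304, 304)
ref = disk_mask(shape, (150, 150), 40)
pred = disk_mask(shape, (158, 150), 40)          # shifted detection
empty = np.zeros(shape, bool)                     # method found nothing
excl = disk_mask(shape, (60, 260), 30)            # artifact-affected corner

pairs = [
    ("shifted detection", pred, None),
    ("empty prediction", empty, None),
    ("shifted + exclusion", pred, excl),
]
per_scan = []
for name, p, e in pairs:
    ms = agreement_metrics(confusion_counts(
        NPAMask(p, PIXEL_PITCH_MM), NPAMask(ref, PIXEL_PITCH_MM), e))
    per_scan.append(ms)
    fmt = lambda v: "UNDEFINED" if v is None else f"{v:.3f}"
    print(f"{name:22s} IoU={fmt(ms.iou)} precision={fmt(ms.precision)} "
          f"recall={fmt(ms.recall)} F1={fmt(ms.f1)}")

print()
print("aggregate (UNDEFINED entries dropped; note the varying n):")
print(aggregate_metrics(per_scan).to_string(index=False))
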