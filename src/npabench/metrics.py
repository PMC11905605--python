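"""Agreement metrics between predicted and reference NPA masks.

Undefined values are explicit: precision is UNDEFINED (None) when the
prediction is empty, recall when the reference is empty, and IoU/F1 when
both are.  Aggregation averages per-scan metrics, drops UNDEFINED entries and
reports the effective n, mirroring grading protocols where some scans yield
no nonperfusion under either method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import NPAMask

__all__ = ["MetricSet", "confusion_counts", "agreement_metrics", "npa_area",
           "evaluate_pair", "aggregate_metrics"]

UNDEFINED = None


@dataclass
class MetricSet:
    """Pixel confusion counts and the four derived agreement statistics."""

    tp: int
    fp: int
    fn: int
    tn: int
    iou: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    area_pred_mm2: float = float("nan")
    area_ref_mm2: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "iou": self.iou, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "area_pred_mm2": self.area_pred_mm2,
            "area_ref_mm2": self.area_ref_mm2,
        }


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, NPAMask):
        return mask.mask
    return np.asarray(mask, bool)


def confusion_counts(
    pred,
    ref,
    exclusion: np.ndarray | None = None,
) -> tuple[int, int, int, int]:
    """Pixel-level (tp, fp, fn, tn); excluded pixels contribute to no count.

    ``pred``/``ref`` may be :class:`NPAMask` objects or boolean arrays.  If
    either carries its own exclusion region it is OR-ed into ``exclusion``.
    """
    excl = np.zeros(_as_bool(pred).shape, bool)
    for m in (pred, ref):
        if isinstance(m, NPAMask) and m.exclusion is not None:
            excl |= m.exclusion
    if exclusion is not None:
        excl |= np.asarray(exclusion, bool)

    p = _as_bool(pred)
    r = _as_bool(ref)
    if p.shape != r.shape or (exclusion is not None and excl.shape != p.shape):
        raise ValueError("pred, ref and exclusion must share dimensions")

    keep = ~excl
    p = p & keep
    r = r & keep
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = int(np.count_nonzero(keep)) - tp - fp - fn
    return tp, fp, fn, tn


def agreement_metrics(counts: tuple[int, int, int, int]) -> MetricSet:
    """IoU, precision, recall, F1 from confusion counts.

    Conventions: precision = tp/(tp+fp), UNDEFINED when tp+fp = 0; recall
    likewise for tp+fn; IoU = tp/(tp+fp+fn) and F1 = 2tp/(2tp+fp+fn), both
    UNDEFINED when the union is empty.  With these limits an empty prediction
    against a nonempty reference gives precision UNDEFINED but recall, IoU
    and F1 all 0.
    """
    tp, fp, fn, tn = counts
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else UNDEFINED
    recall = tp / (tp + fn) if tp + fn > 0 else UNDEFINED
    union = tp + fp + fn
    iou = tp / union if union > 0 else UNDEFINED
    f1 = 2 * tp / (2 * tp + fp + fn) if union > 0 else UNDEFINED
    return MetricSet(tp=tp, fp=fp, fn=fn, tn=tn, iou=iou,
                     precision=precision, recall=recall, f1=f1)


def npa_area(mask: NPAMask) -> float:
    """NPA in mm^2: included (non-excluded) pixel count x pixel pitch squared."""
    return mask.area_mm2


def evaluate_pair(
    pred: NPAMask,
    ref: NPAMask,
    exclusion: np.ndarray | None = None,
) -> MetricSet:
    """Full agreement evaluation of one (prediction, reference) mask pair."""
    ms = agreement_metrics(confusion_counts(pred, ref, exclusion))
    ms.area_pred_mm2 = pred.area_mm2
    ms.area_ref_mm2 = ref.area_mm2
    return ms


def aggregate_metrics(per_scan: list[MetricSet]) -> pd.DataFrame:
    """Per-scan averaging with UNDEFINED entries dropped.

    Returns one row per metric with the defined-entry count ``n`` (which can
    differ between metrics), mean and sd.
    """
    rows = []
    for name in ("iou", "precision", "recall", "f1"):
        vals = [getattr(m, name) for m in per_scan]
        defined = np.array([v for v in vals if v is not UNDEFINED], float)
        rows.append(
            {
                "metric": name,
                "n": int(defined.size),
                "mean": float(defined.mean()) if defined.size else float("nan"),
                "sd": float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
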