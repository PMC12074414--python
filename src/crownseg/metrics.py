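"""Pixel-wise segmentation metrics over a 3-class confusion table.

Classes are 0 background, 1 conifer (*Pinus tabuliformis*), 2 broadleaf
(*Salix matsudana*).  From a truth-by-prediction count matrix the standard
quantities follow per class i:

    TP_i = counts[i, i]          FP_i = column sum - TP_i
    FN_i = row sum - TP_i        TN_i = total - TP_i - FP_i - FN_i

and the reported metrics are

    PA    = trace / total                     (overall pixel accuracy)
    CPA_i = TP_i / (TP_i + FP_i)              (per-class accuracy, precision form)
    MPA   = mean_i CPA_i
    IoU_i = TP_i / (TP_i + FP_i + FN_i)
    MIoU  = mean_i IoU_i

A class that is absent from a ratio's denominator is undefined for that
metric and is excluded from the corresponding mean, so a perfect prediction
scores MPA = MIoU = 1 even when a class never occurs.  Whether the reported
means should include the background class is a reporting convention;
:func:`summarize` therefore gives both the with-background and
foreground-only means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ConfusionTable",
    "accumulate",
    "pixel_accuracy",
    "class_pixel_accuracy",
    "mean_pixel_accuracy",
    "iou",
    "mean_iou",
    "summarize",
    "CLASS_NAMES",
]

CLASS_NAMES = ("background", "pinus", "salix")


@dataclass
class ConfusionTable:
    """n-by-n pixel counts, rows = truth class, cols = predicted class."""

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 3), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion table must be square")
        if (self.counts < 0).any():
            raise ValueError("negative pixel counts")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fp(i) - self.fn(i)

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(self.counts + other.counts)


def accumulate(pred, truth, ct: Optional[ConfusionTable] = None, n: int = 3) -> ConfusionTable:
    """Add one (prediction, truth) mask pair into a confusion table.

    Accumulation is additive: folding many tiles one by one equals folding
    their concatenation.
    """
    p = np.asarray(pred).ravel()
    t = np.asarray(truth).ravel()
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if ct is None:
        ct = ConfusionTable(np.zeros((n, n), dtype=np.int64))
    n = ct.n
    if p.size:
        if p.min() < 0 or p.max() >= n or t.min() < 0 or t.max() >= n:
            raise ValueError(f"labels must lie in [0, {n})")
        ct.counts += np.bincount(
            t.astype(np.int64) * n + p.astype(np.int64), minlength=n * n
        ).reshape(n, n)
    return ct


def pixel_accuracy(ct: ConfusionTable) -> float:
    """Fraction of correctly labelled pixels (trace over total)."""
    if ct.total == 0:
        raise ValueError("pixel accuracy undefined on an empty table")
    return float(np.trace(ct.counts) / ct.total)


def class_pixel_accuracy(ct: ConfusionTable, i: int) -> float:
    """Per-class pixel accuracy in its precision form, TP/(TP+FP).

    NaN when the class was never predicted (undefined ratio).
    """
    denom = ct.tp(i) + ct.fp(i)
    return ct.tp(i) / denom if denom else math.nan


def mean_pixel_accuracy(ct: ConfusionTable, classes: Optional[list[int]] = None) -> float:
    """Unweighted mean CPA over classes where it is defined."""
    vals = [
        class_pixel_accuracy(ct, i)
        for i in (classes if classes is not None else range(ct.n))
    ]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        raise ValueError("no class has a defined pixel accuracy")
    return float(np.mean(vals))


def iou(ct: ConfusionTable, i: int) -> float:
    """Intersection over union, TP/(TP+FP+FN); NaN when the union is empty."""
    denom = ct.tp(i) + ct.fp(i) + ct.fn(i)
    return ct.tp(i) / denom if denom else math.nan


def mean_iou(ct: ConfusionTable, classes: Optional[list[int]] = None) -> float:
    """Unweighted mean IoU over classes with a nonzero union."""
    vals = [iou(ct, i) for i in (classes if classes is not None else range(ct.n))]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        raise ValueError("no class has a defined IoU")
    return float(np.mean(vals))


def summarize(ct: ConfusionTable) -> dict:
    """All metrics in one JSON-friendly dict (NaN-valued entries omitted)."""
    per_class = {}
    for i in range(ct.n):
        name = CLASS_NAMES[i] if i < len(CLASS_NAMES) else str(i)
        entry = {}
        cpa = class_pixel_accuracy(ct, i)
        jac = iou(ct, i)
        if not math.isnan(cpa):
            entry["cpa"] = cpa
        if not math.isnan(jac):
            entry["iou"] = jac
        per_class[name] = entry
    fg = list(range(1, ct.n))
    out = {
        "pixel_accuracy": pixel_accuracy(ct),
        "mean_pixel_accuracy": mean_pixel_accuracy(ct),
        "mean_iou": mean_iou(ct),
        "per_class": per_class,
        "total_pixels": ct.total,
    }
    try:
        out["mean_pixel_accuracy_foreground"] = mean_pixel_accuracy(ct, fg)
        out["mean_iou_foreground"] = mean_iou(ct, fg)
    except ValueError:
        pass
    return out
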