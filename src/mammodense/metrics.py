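"""Pixel-level segmentation metrics: Dice index, pixel accuracy, IoU.

All three derive from TP/FP/FN/TN confusion counts between a predicted
and a true binary tumor mask:

    DI  = 2 TP / (2 TP + FP + FN)
    PA  = TP / (TP + FN)          (foreground recall, not global accuracy)
    IOU = TP / (TP + FN + FP)

DI and IoU are linked by the identity DI = 2 IoU / (1 + IoU).  When both
masks are empty, all metrics are defined as 1 (perfect agreement) and a
warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred_mask: np.ndarray,
                     true_mask: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between two binary masks of equal shape."""
    pred = np.asarray(pred_mask).astype(bool)
    true = np.asarray(true_mask).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _empty_warn(what: str) -> float:
    warnings.warn(f"{what}: both masks empty; metric defined as 1",
                  stacklevel=3)
    return 1.0


def dice_index(c: ConfusionCounts) -> float:
    """DI = 2TP / (2TP + FP + FN); 1 when pred and truth are both empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return _empty_warn("dice_index")
    return 2 * c.tp / denom


def pixel_accuracy(c: ConfusionCounts) -> float:
    """PA = TP / (TP + FN): the fraction of true tumor pixels recovered."""
    denom = c.tp + c.fn
    if denom == 0:
        return _empty_warn("pixel_accuracy")
    return c.tp / denom


def iou(c: ConfusionCounts) -> float:
    """IoU = TP / (TP + FN + FP); always <= DI."""
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        return _empty_warn("iou")
    return c.tp / denom


@dataclass
class MetricReport:
    """Per-image DI/PA/IoU rows plus their arithmetic means."""

    per_image: list[tuple[str, float, float, float]] = field(
        default_factory=list)
    mean_di: float = float("nan")
    mean_iou: float = float("nan")
    mean_pa: float = float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image,
                            columns=["image_id", "DI", "PA", "IOU"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MetricReport":
        df = pd.read_csv(path)
        rows = [(str(r.image_id), float(r.DI), float(r.PA), float(r.IOU))
                for r in df.itertuples()]
        return _aggregate(rows)


def _aggregate(rows) -> MetricReport:
    dis = [r[1] for r in rows]
    pas = [r[2] for r in rows]
    ious = [r[3] for r in rows]
    return MetricReport(per_image=rows,
                        mean_di=float(np.mean(dis)),
                        mean_pa=float(np.mean(pas)),
                        mean_iou=float(np.mean(ious)))


def evaluate_set(pairs, ids=None, pooled: bool = False) -> MetricReport:
    """Evaluate (pred, truth) mask pairs into a metric report.

    Default aggregation is the per-image arithmetic mean; ``pooled``
    instead sums confusion counts over the whole set before computing
    each metric once.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty evaluation set")
    if ids is None:
        ids = [str(i) for i in range(len(pairs))]
    rows = []
    totals = ConfusionCounts(0, 0, 0, 0)
    for img_id, (pred, truth) in zip(ids, pairs):
        c = confusion_counts(pred, truth)
        rows.append((img_id, dice_index(c), pixel_accuracy(c), iou(c)))
        totals = ConfusionCounts(totals.tp + c.tp, totals.fp + c.fp,
                                 totals.fn + c.fn, totals.tn + c.tn)
    report = _aggregate(rows)
    if pooled:
        report.mean_di = dice_index(totals)
        report.mean_pa = pixel_accuracy(totals)
        report.mean_iou = iou(totals)
    return report
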