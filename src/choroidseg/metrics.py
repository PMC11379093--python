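"""Segmentation metrics from pixel confusion counts.

For a class treated as positive with per-pixel tallies TP/FP/TN/FN:

    IoU  = TP / (TP + FP + FN)
    Dice = 2 TP / (2 TP + FP + FN)
    Acc  = (TP + TN) / (TP + TN + FP + FN)

``m``-prefixed scores are the unweighted mean of the per-class scores over
the two classes (background, choroid).  Counts are accumulated over the whole
evaluated split before the ratios are formed (dataset-level aggregation, the
convention of standard semantic-segmentation tooling); per-image averaging is
available behind a flag.  Scores are kept in [0, 1]; multiply by 100 for the
conventional percentage scale.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SegReport",
    "confusion_counts",
    "class_metrics",
    "mean_metrics",
]

BACKGROUND, CHOROID = 0, 1
_CLASSES = (BACKGROUND, CHOROID)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies for one class treated as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass
class SegReport:
    """Per-class and mean Dice / IoU / pixel-accuracy for one evaluated split."""

    per_class: dict = field(default_factory=dict)
    mDice: float = float("nan")
    mIoU: float = float("nan")
    mAcc: float = float("nan")

    def scaled(self) -> dict:
        """Scores on the conventional x100 (percent) scale."""
        return {
            "mDice": 100.0 * self.mDice,
            "mIoU": 100.0 * self.mIoU,
            "mAcc": 100.0 * self.mAcc,
        }

    def to_dict(self) -> dict:
        return {
            "mDice": self.mDice,
            "mIoU": self.mIoU,
            "mAcc": self.mAcc,
            "per_class": {str(k): dict(v) for k, v in self.per_class.items()},
        }

    def write_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def write_csv(self, path, label: str = "split"):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["split", "mDice", "mIoU", "mAcc"])
            w.writerow([label, self.mDice, self.mIoU, self.mAcc])

    def __str__(self):
        s = self.scaled()
        return (
            f"mDice {s['mDice']:.2f}  mIoU {s['mIoU']:.2f}  mAcc {s['mAcc']:.2f}"
        )


def _check_mask(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, _CLASSES).all():
        raise ValueError(f"{name} contains labels outside {{0, 1}}: {vals}")
    return mask


def confusion_counts(pred_mask, true_mask, class_id: int) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over all pixels with ``class_id`` as positive."""
    pred = _check_mask(pred_mask, "pred_mask")
    true = _check_mask(true_mask, "true_mask")
    if pred.shape != true.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {true.shape}"
        )
    if class_id not in _CLASSES:
        raise ValueError(f"class_id must be one of {_CLASSES}")
    pp = pred == class_id
    tt = true == class_id
    return ConfusionCounts(
        tp=int(np.count_nonzero(pp & tt)),
        fp=int(np.count_nonzero(pp & ~tt)),
        tn=int(np.count_nonzero(~pp & ~tt)),
        fn=int(np.count_nonzero(~pp & tt)),
    )


def class_metrics(c: ConfusionCounts) -> dict:
    """Dice, IoU and accuracy for one class.

    If the class occurs in neither prediction nor truth (tp+fp+fn = 0) the
    overlap scores are 1 by convention, with a warning: the class was
    trivially segmented perfectly, and NaNs would poison split-level means on
    degenerate crops.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn(
            "class absent from both masks; dice = iou = 1 by convention",
            stacklevel=2,
        )
        iou = dice = 1.0
    else:
        iou = c.tp / denom
        dice = 2.0 * c.tp / (2.0 * c.tp + c.fp + c.fn)
    acc = (c.tp + c.tn) / c.total
    return {"dice": dice, "iou": iou, "acc": acc}


def mean_metrics(preds, truths, per_image: bool = False) -> SegReport:
    """Aggregate metrics over paired lists of predicted and true masks.

    By default confusion counts are pooled over all images per class before
    the ratios are formed; ``per_image=True`` instead averages the per-image
    scores.
    """
    preds, truths = list(preds), list(truths)
    if not preds or len(preds) != len(truths):
        raise ValueError("need equally sized, non-empty mask lists")

    if per_image:
        acc: dict[int, dict[str, list]] = {
            k: {"dice": [], "iou": [], "acc": []} for k in _CLASSES
        }
        for p, t in zip(preds, truths):
            for k in _CLASSES:
                m = class_metrics(confusion_counts(p, t, k))
                for key in acc[k]:
                    acc[k][key].append(m[key])
        per_class = {
            k: {key: float(np.mean(vals)) for key, vals in acc[k].items()}
            for k in _CLASSES
        }
    else:
        totals = {k: ConfusionCounts(0, 0, 0, 0) for k in _CLASSES}
        for p, t in zip(preds, truths):
            for k in _CLASSES:
                totals[k] = totals[k] + confusion_counts(p, t, k)
        per_class = {k: class_metrics(totals[k]) for k in _CLASSES}

    return SegReport(
        per_class=per_class,
        mDice=float(np.mean([per_class[k]["dice"] for k in _CLASSES])),
        mIoU=float(np.mean([per_class[k]["iou"] for k in _CLASSES])),
        mAcc=float(np.mean([per_class[k]["acc"] for k in _CLASSES])),
    )
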