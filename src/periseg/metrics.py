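"""Segmentation evaluation: overlap ratios and pixel confusion counts.

Conventions for degenerate inputs (never addressed by most references):
both masks empty gives Jaccard = Dice = 1 (perfect agreement that nothing
is present); a zero denominator in precision or recall yields 0 and the
corresponding ``*_defined`` flag is set to ``False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BinaryMask, as_bool_mask, check_same_shape

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "confusion_counts",
    "jaccard",
    "dice",
    "precision",
    "recall",
    "evaluate",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel (or case) level confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegmentationMetrics:
    jaccard: float
    dice: float
    precision: float
    recall: float
    counts: ConfusionCounts
    precision_defined: bool = True
    recall_defined: bool = True


def confusion_counts(gold: BinaryMask, pred: BinaryMask) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between a gold mask and a prediction."""
    gold = as_bool_mask(gold)
    pred = as_bool_mask(pred)
    check_same_shape(gold, pred, "gold and predicted masks")
    tp = int(np.count_nonzero(gold & pred))
    fp = int(np.count_nonzero(~gold & pred))
    fn = int(np.count_nonzero(gold & ~pred))
    tn = int(gold.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def jaccard(gold: BinaryMask, pred: BinaryMask) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    c = confusion_counts(gold, pred)
    union = c.tp + c.fp + c.fn
    if union == 0:
        return 1.0
    return c.tp / union


def dice(gold: BinaryMask, pred: BinaryMask) -> float:
    """Dice overlap 2|C∩D|/(|C|+|D|); 1.0 when both masks are empty."""
    c = confusion_counts(gold, pred)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def precision(counts: ConfusionCounts) -> float:
    """TP/(TP+FP); 0.0 when the denominator is zero."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    """TP/(TP+FN); 0.0 when the denominator is zero."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def evaluate(gold: BinaryMask, pred: BinaryMask) -> SegmentationMetrics:
    """Bundle Jaccard, Dice, precision and recall for one mask pair."""
    c = confusion_counts(gold, pred)
    union = c.tp + c.fp + c.fn
    j = 1.0 if union == 0 else c.tp / union
    d = 1.0 if union == 0 else 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return SegmentationMetrics(
        jaccard=j,
        dice=d,
        precision=precision(c),
        recall=recall(c),
        counts=c,
        precision_defined=(c.tp + c.fp) > 0,
        recall_defined=(c.tp + c.fn) > 0,
    )


def evaluate_cohort(
    pairs: list[tuple[BinaryMask, BinaryMask]],
) -> tuple[list[SegmentationMetrics], dict[str, float]]:
    """Per-slice metrics plus their macro-average across the cohort."""
    if not pairs:
        raise ValueError("empty cohort")
    rows = [evaluate(g, p) for g, p in pairs]
    mean = {
        k: float(np.mean([getattr(r, k) for r in rows]))
        for k in ("jaccard", "dice", "precision", "recall")
    }
    return rows, mean
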