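"""Evaluation metrics: per-class confusion counts, IoU, Dice, accuracy,
binomial confidence intervals and precision–recall AUC.

Segmentation is scored one-vs-rest per class at the pixel level:
IoU_i = TP_i/(TP_i+FP_i+FN_i), Dice_i = 2TP_i/(2TP_i+FP_i+FN_i). A class
absent from both prediction and truth scores 1.0 by convention (the 0/0
case). Detection uses accuracy with a binomial confidence interval and
PR-AUC over the score threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

from .mask_codec import LabelMask

__all__ = [
    "EvalCounts",
    "confusion_counts",
    "iou",
    "dice",
    "accuracy",
    "binomial_ci",
    "pr_auc",
    "segmentation_report",
    "mean_foreground_iou",
]


@dataclass(frozen=True)
class EvalCounts:
    """One-vs-rest pixel (or sample) counts for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred: LabelMask, truth: LabelMask, class_index: int) -> EvalCounts:
    """Pixel-level one-vs-rest counts for one class."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if class_index >= max(pred.K, truth.K) or class_index < 0:
        raise ValueError(f"class_index {class_index} out of range")
    p = pred.labels == class_index
    t = truth.labels == class_index
    return EvalCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def iou(c: EvalCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0  # class absent everywhere: treat as perfect agreement
    return c.tp / denom


def dice(c: EvalCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def accuracy(c: EvalCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return (c.tp + c.tn) / c.total


def binomial_ci(acc: float, n: int, level: float = 0.95,
                method: str = "normal") -> tuple[float, float]:
    """Confidence interval for a proportion, clipped to [0, 1].

    ``method='normal'`` is the usual acc ± z·sqrt(acc(1−acc)/n); Wilson
    is available for small n or extreme proportions.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if not (0.0 <= acc <= 1.0):
        raise ValueError(f"acc must lie in [0, 1], got {acc}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(acc * (1.0 - acc) / n)
        return (max(0.0, acc - half), min(1.0, acc + half))
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(round(acc * n), n, alpha=1.0 - level, method="wilson")
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


def pr_auc(scores, labels) -> float:
    """Area under the precision–recall curve (step-wise interpolation).

    ``scores`` are probabilities of the positive class; ``labels`` are
    0/1. Equivalent to average precision: the precision achieved at each
    recall increment, weighted by the recall step.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not np.any(labels == 1):
        raise ValueError("PR-AUC undefined without at least one positive label")
    return float(average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# aggregation helpers
# ---------------------------------------------------------------------------

def segmentation_report(preds, truths, K: int) -> dict:
    """Dataset-level per-class IoU/Dice from pooled confusion counts."""
    per_class = []
    for k in range(K):
        c = EvalCounts(0, 0, 0, 0)
        for p, t in zip(preds, truths):
            c = c + confusion_counts(p, t, k)
        per_class.append({"class": k, "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                          "iou": iou(c), "dice": dice(c)})
    return {"per_class": per_class,
            "mean_iou": float(np.mean([r["iou"] for r in per_class])),
            "mean_dice": float(np.mean([r["dice"] for r in per_class]))}


def multi_run_summary(values) -> dict:
    """Summary across repeated runs of one experiment.

    Reports every run plus the max (a best-of-n reporting convention) and the mean (which guards against cherry-picking)."""
    values = [float(v) for v in values]
    if not values:
        raise ValueError("need at least one run")
    return {"runs": values, "max": max(values), "mean": float(np.mean(values))}


def mean_foreground_iou(preds, truths, K: int) -> float:
    """Mean IoU over classes 1..K−1 (class 0 is background/'other')."""
    report = segmentation_report(preds, truths, K)
    fg = [r["iou"] for r in report["per_class"][1:]]
    return float(np.mean(fg)) if fg else 1.0
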