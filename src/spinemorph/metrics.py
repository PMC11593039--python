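"""Evaluation statistics for segmentation masks and vertebra-wise classification.

Two families of metrics are provided:

* pixel-wise overlap between a predicted and a reference binary mask
  (Dice similarity coefficient and its false-negative / false-positive
  decomposition, IoU, and the pixel-wise confusion metrics), and
* vertebra-wise classification metrics (sensitivity, specificity, accuracy,
  precision, F1) with exact Clopper-Pearson binomial confidence intervals,
  plus ROC curves and the area under them.

The Dice decomposition satisfies the identities ``DSC = F1``,
``DSC = 1 - (FND + FPD) / 2`` and ``IoU = DSC / (2 - DSC)`` exactly; these
are asserted by the test suite on arbitrary mask pairs.

AUROC is computed by trapezoidal integration of the empirical ROC curve,
which equals the Mann-Whitney U statistic normalised by ``n_pos * n_neg``
with ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "MetricReport",
    "SegOverlapReport",
    "seg_overlap",
    "classification_metrics",
    "clopper_pearson",
    "roc_curve",
    "auroc",
    "format_percent",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of a binary classifier."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, truth: Sequence[bool], predicted: Sequence[bool]) -> "ConfusionCounts":
        t = np.asarray(truth, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        if t.shape != p.shape:
            raise InvalidInputError(
                f"truth and prediction have different lengths: {t.shape} vs {p.shape}"
            )
        return cls(
            tp=int(np.sum(t & p)),
            tn=int(np.sum(~t & ~p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
        )

    def to_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with an optional two-sided confidence interval.

    ``value`` is NaN when the metric is undefined for the given counts
    (zero denominator); the interval bounds are then NaN as well.
    """

    value: float
    lower: float = math.nan
    upper: float = math.nan

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)

    def as_percent(self) -> tuple[float, float, float]:
        return (
            format_percent(self.value),
            format_percent(self.lower),
            format_percent(self.upper),
        )


@dataclass(frozen=True)
class MetricReport:
    """Classification metrics with 95% (or configured) confidence intervals."""

    counts: ConfusionCounts
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    accuracy: MetricEstimate
    precision: MetricEstimate
    f1: MetricEstimate
    ci_level: float = 0.95
    auroc: float | None = None

    def to_dict(self, percent: bool = True) -> dict:
        def fmt(est: MetricEstimate) -> dict:
            v, lo, hi = est.as_percent() if percent else (est.value, est.lower, est.upper)
            return {"value": v, "ci_lower": lo, "ci_upper": hi}

        out = {
            "confusion": self.counts.to_dict(),
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
            "accuracy": fmt(self.accuracy),
            "precision": fmt(self.precision),
            "f1": fmt(self.f1),
            "ci_level": self.ci_level,
        }
        if self.auroc is not None:
            out["auroc"] = round(self.auroc, 3)
        return out


@dataclass(frozen=True)
class SegOverlapReport:
    """Pixel-wise overlap metrics between a predicted and a reference mask."""

    dsc: float
    fnd: float
    fpd: float
    iou: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    counts: ConfusionCounts = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "DSC": self.dsc,
            "FND": self.fnd,
            "FPD": self.fpd,
            "IoU": self.iou,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "F1": self.f1,
            "accuracy": self.accuracy,
        }


def format_percent(x: float) -> float:
    """Express a proportion as a percentage rounded to two decimals.

    Uses round-half-even, the rounding applied throughout reported tables.
    """
    if math.isnan(x):
        return math.nan
    return round(100.0 * x, 2)


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise InvalidInputError(f"{name} is not binary (values {uniq[:10]})")
    return arr.astype(bool)


def seg_overlap(pred: np.ndarray, truth: np.ndarray) -> SegOverlapReport:
    """Pixel-wise overlap report between predicted and reference binary masks.

    DSC = 2TP/(2TP+FP+FN); FND = 2FN/(2TP+FP+FN); FPD = 2FP/(2TP+FP+FN);
    IoU = TP/(TP+FP+FN). Sensitivity, specificity, F1 and accuracy are the
    pixel-wise confusion metrics over the same counts.
    """
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise InvalidInputError(f"mask shapes differ: {p.shape} vs {t.shape}")
    if not p.any() and not t.any():
        raise UndefinedMetricError("both masks are empty; overlap metrics are undefined")

    c = ConfusionCounts.from_labels(t.ravel(), p.ravel())
    denom = 2 * c.tp + c.fp + c.fn  # > 0 since not both masks empty
    dsc = 2 * c.tp / denom
    fnd = 2 * c.fn / denom
    fpd = 2 * c.fp / denom
    iou = c.tp / (c.tp + c.fp + c.fn)
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else math.nan
    acc = (c.tp + c.tn) / c.total
    return SegOverlapReport(
        dsc=dsc, fnd=fnd, fpd=fpd, iou=iou,
        sensitivity=sens, specificity=spec, f1=dsc, accuracy=acc, counts=c,
    )


def clopper_pearson(successes: int, trials: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion."""
    if trials <= 0:
        raise InvalidInputError("trials must be positive")
    if not 0 <= successes <= trials:
        raise InvalidInputError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - ci_level, method="beta")
    return float(lo), float(hi)


def _proportion_estimate(k: int, n: int, ci_level: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan)
    lo, hi = clopper_pearson(k, n, ci_level)
    return MetricEstimate(k / n, lo, hi)


def classification_metrics(
    counts: ConfusionCounts,
    ci_level: float = 0.95,
    auroc: float | None = None,
) -> MetricReport:
    """Vertebra-wise classification metrics with exact binomial CIs.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total, precision = TP/(TP+FP); each treated as a
    binomial proportion over its own denominator for the Clopper-Pearson
    interval (accuracy over the full cohort size). A metric with a zero
    denominator is reported as NaN rather than raising.
    """
    c = counts
    if c.total == 0:
        raise InvalidInputError("confusion counts sum to zero")
    sens = _proportion_estimate(c.tp, c.tp + c.fn, ci_level)
    spec = _proportion_estimate(c.tn, c.tn + c.fp, ci_level)
    acc = _proportion_estimate(c.tp + c.tn, c.total, ci_level)
    prec = _proportion_estimate(c.tp, c.tp + c.fp, ci_level)
    f1_denom = 2 * c.tp + c.fp + c.fn
    f1 = MetricEstimate(2 * c.tp / f1_denom) if f1_denom else MetricEstimate(math.nan)
    return MetricReport(
        counts=c, sensitivity=sens, specificity=spec, accuracy=acc,
        precision=prec, f1=f1, ci_level=ci_level, auroc=auroc,
    )


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be 1-D and the same length")
    if y.all() or not y.any():
        raise UndefinedMetricError("ROC requires at least one positive and one negative label")
    return s, y


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC curve: (FPR, TPR, thresholds), thresholds descending.

    Thresholds are the unique score values plus a leading sentinel above the
    maximum; TPR and FPR are monotone non-decreasing along the curve.
    """
    s, y = _check_scores_labels(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    return fpr, tpr, thr


def auroc(scores, labels) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equivalent to the probability that a random positive outscores a random
    negative, with ties counted one half (Mann-Whitney convention).
    """
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))
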