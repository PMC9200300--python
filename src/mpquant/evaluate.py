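"""Pixel-level metrics, annotator mask fusion, and recovery assessment.

Segmentation quality is scored per image from the pixel confusion counts
(TP = MP predicted MP, FP = background predicted MP, FN = MP missed) with
five standard metrics: balanced accuracy, recall, precision, F1, IoU.
Final effectiveness is the unweighted mean over test images and, for
cross-validated models, the mean of the four fold means.

Recovery assessment speaks the language of environmental monitoring:
``recovery = 100 * predicted MP count / ground-truth MP count``, rounded
half-away-from-zero to an integer percentage per sample, then aggregated
as mean and sample standard deviation (n - 1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_core import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RecoveryReport",
    "confusion",
    "metrics",
    "mean_metrics",
    "majority_vote",
    "recovery",
    "recovery_report",
    "estimation_tally",
]

METRIC_NAMES = ("balanced_accuracy", "recall", "precision", "f1", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """One row of metric values; ``undefined`` flags zero-denominator ratios
    that were reported as 0 so that means stay defined."""

    balanced_accuracy: float
    recall: float
    precision: float
    f1: float
    iou: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class RecoveryReport:
    """Per-sample integer recoveries plus mean and sample SD (percent)."""

    ground_truth: list[int]
    predicted: list[int]
    recoveries: list[int]
    mean: float
    sd: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ground_truth": self.ground_truth,
                "predicted": self.predicted,
                "recovery_pct": self.recoveries,
            }
        )


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion tally between predicted and ground-truth masks."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, undefined: set[str], name: str) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Balanced accuracy, recall, precision, F1 and IoU from counts."""
    undef: set[str] = set()
    rec = _ratio(c.tp, c.tp + c.fn, undef, "recall")
    prec = _ratio(c.tp, c.tp + c.fp, undef, "precision")
    spec = _ratio(c.tn, c.tn + c.fp, undef, "balanced_accuracy")
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, undef, "iou")
    if prec + rec > 0:
        f1 = 2 * prec * rec / (prec + rec)
    else:
        undef.add("f1")
        f1 = 0.0
    bal = (rec + spec) / 2.0
    return MetricReport(
        balanced_accuracy=bal, recall=rec, precision=prec, f1=f1, iou=iou,
        undefined=frozenset(undef),
    )


def mean_metrics(
    reports: Sequence[MetricReport],
    folds: Sequence[Sequence[int]] | None = None,
) -> MetricReport:
    """Unweighted per-metric mean; with ``folds`` (index groups), the mean
    of fold means — which differs from the pooled mean when folds are
    unequal in size."""
    if not reports:
        raise ValueError("need at least one metric row")
    if folds is None:
        vals = {
            name: float(np.mean([getattr(r, name) for r in reports]))
            for name in METRIC_NAMES
        }
    else:
        fold_means = [mean_metrics([reports[i] for i in fold]) for fold in folds]
        vals = {
            name: float(np.mean([getattr(m, name) for m in fold_means]))
            for name in METRIC_NAMES
        }
    return MetricReport(**vals)


def majority_vote(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Pixel-wise majority fusion of annotator masks.

    A pixel is foreground iff strictly more than half the masks mark it;
    with an even count, ties go to background.
    """
    if len(masks) < 2:
        raise ValueError("majority vote needs at least two masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all masks must share a shape")
    votes = np.sum([m.pixels for m in masks], axis=0)
    return BinaryMask(pixels=(votes > len(masks) / 2).astype(np.uint8))


def recovery(predicted: int, ground_truth: int) -> int:
    """Integer percentage recovery, rounded half-away-from-zero.

    ``recovery(175, 170) == 103``; exact multiples are exact
    (``recovery(k*g, g) == 100*k``).
    """
    if ground_truth < 1:
        raise ValueError("undefined recovery: ground truth count must be >= 1")
    if predicted < 0:
        raise ValueError("predicted count must be non-negative")
    # exact integer round-half-away-from-zero of 100 * predicted / ground_truth
    return (200 * predicted + ground_truth) // (2 * ground_truth)


def recovery_report(pairs: Sequence[tuple[int, int]]) -> RecoveryReport:
    """Aggregate (ground_truth, predicted) pairs into a recovery report.

    Mean is over the per-sample integer recoveries; SD uses the n - 1
    denominator and requires at least two pairs (None otherwise).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one (ground_truth, predicted) pair")
    gts = [int(g) for g, _ in pairs]
    preds = [int(p) for _, p in pairs]
    recs = [recovery(p, g) for g, p in zip(gts, preds)]
    mean = float(np.mean(recs))
    sd = float(np.std(recs, ddof=1)) if len(recs) >= 2 else None
    return RecoveryReport(
        ground_truth=gts, predicted=preds, recoveries=recs, mean=mean, sd=sd
    )


def estimation_tally(pairs: Sequence[tuple[int, int]]) -> dict[str, int]:
    """Count under-, exact and over-estimations among (gt, pred) pairs."""
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    tally = {"under": 0, "exact": 0, "over": 0}
    for g, p in pairs:
        key = "under" if p < g else ("exact" if p == g else "over")
        tally[key] += 1
    return tally
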