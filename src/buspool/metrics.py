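"""Sequence-level evaluation: confusion counts, accuracy/precision/recall/F1, AUC.

Malignant is the positive class throughout.  Metrics with a zero
denominator are reported as *undefined* (None, with a flag) rather than
silently coerced to 0, which would distort small-sample evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .frame_io import VALID_LABELS

POSITIVE = "malignant"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must cover at least one item")


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    @property
    def undefined(self) -> dict:
        return {
            name: getattr(self, name) is None
            for name in ("accuracy", "precision", "recall", "f1")
        }


def _check_labels(labels: Sequence[str]) -> None:
    bad = set(labels) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {VALID_LABELS}")


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN with malignant as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    if len(true_labels) == 0:
        raise ValueError("cannot build a confusion matrix from empty label lists")
    _check_labels(true_labels)
    _check_labels(predicted_labels)
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == POSITIVE:
            if p == POSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    accuracy  = (TP+TN) / (P+N)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    F1        = TP / (TP + (FP+FN)/2)
    """
    total = counts.tp + counts.tn + counts.fp + counts.fn

    def safe(num: float, den: float) -> Optional[float]:
        return num / den if den > 0 else None

    return ClassificationMetrics(
        accuracy=safe(counts.tp + counts.tn, total),
        precision=safe(counts.tp, counts.tp + counts.fp),
        recall=safe(counts.tp, counts.tp + counts.fn),
        f1=safe(counts.tp, counts.tp + 0.5 * (counts.fp + counts.fn)),
    )


def roc_auc(scores: Sequence[float], true_labels: Sequence[str]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic.

    Equivalent to trapezoidal integration over all thresholds; tied scores
    contribute 1/2 per positive-negative pair.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(true_labels):
        raise ValueError("scores and labels differ in length")
    _check_labels(true_labels)
    y = np.array([1 if t == POSITIVE else 0 for t in true_labels])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
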