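"""Evaluation metrics for simulation benchmarks.

Precision, recall and F1 follow the standard retrieval definitions;
``precision = 1 − observed FDR`` by construction, so the observed FDR of
a caller on simulated truth is read directly off the confusion counts.
All 0/0 cases (no calls, no positives) return 0 so metric curves stay
total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionCounts",
    "confusion",
    "f1",
    "precision_recall",
    "type1_error",
    "observed_fdr",
    "roc_points",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def confusion(truth: np.ndarray, called: np.ndarray) -> ConfusionCounts:
    """Standard 2x2 tally of boolean truth vs boolean calls."""
    truth = np.asarray(truth, dtype=bool)
    called = np.asarray(called, dtype=bool)
    if truth.shape != called.shape:
        raise ValueError("truth and called must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(truth & called)),
        fp=int(np.sum(~truth & called)),
        fn=int(np.sum(truth & ~called)),
        tn=int(np.sum(~truth & ~called)),
    )


def f1(c: ConfusionCounts) -> float:
    """F1 = 2·tp / (2·tp + fn + fp); 0 when there is nothing to score."""
    denom = 2 * c.tp + c.fn + c.fp
    return 2 * c.tp / denom if denom > 0 else 0.0


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    return precision, recall


def type1_error(null_p: np.ndarray, alpha: float) -> float:
    """Fraction of known-null p-values below alpha."""
    null_p = np.asarray(null_p, dtype=float)
    if null_p.size == 0:
        return 0.0
    return float(np.mean(null_p < alpha))


def observed_fdr(truth: np.ndarray, called: np.ndarray) -> float:
    """fp/(tp+fp) against simulation truth; 0 when nothing is called."""
    c = confusion(truth, called)
    return c.fp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0


def roc_points(scores: np.ndarray, truth: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) staircase over score thresholds, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if truth.all() or not truth.any():
        # one class only: the staircase degenerates to the diagonal corners
        return [(0.0, 0.0), (1.0, 1.0)]
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    return list(zip(fpr.tolist(), tpr.tolist()))
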