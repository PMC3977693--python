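"""Structure-recovery scoring of an inferred network.

An estimated coefficient matrix is converted to a binary adjacency by
thresholding coefficient magnitudes, then compared entrywise (diagonal
self-regulation included) against the true adjacency.  Reported metrics:

    TPR = TP / (TP + FN)    true positive rate (recall)
    FPR = FP / (FP + TN)    false positive rate
    PPV = TP / (TP + FP)    positive predictive value (precision)

Undefined ratios (zero denominator) are reported as NaN, never as 0/0.

Scoring can be sign-blind (boolean adjacencies: a link is a link) or
sign-aware (signed adjacencies in {-1, 0, +1}: a predicted link on a true
edge counts as a true positive only when the regulation sign matches;
with the wrong sign it counts as a false positive, since an incorrect
interaction was predicted).  The Monte-Carlo benchmark uses sign-aware
scoring; that is the only reading under which the reference per-run count
identities (TP+FN below the true link count, FP+TN above the non-link
count, by the same amount) are arithmetically possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "ConfusionCounts",
    "EvaluationMetrics",
    "call_links",
    "signed_links",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def metrics(self) -> "EvaluationMetrics":
        return EvaluationMetrics(
            tpr=_ratio(self.tp, self.tp + self.fn),
            fpr=_ratio(self.fp, self.fp + self.tn),
            ppv=_ratio(self.tp, self.tp + self.fp),
        )


@dataclass(frozen=True)
class EvaluationMetrics:
    tpr: float
    fpr: float
    ppv: float


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def call_links(A_hat: NDArray[np.float64], tau: float) -> NDArray[np.bool_]:
    """Call entry (i, j) a link iff ``|a_ij| > tau``."""
    if tau < 0:
        raise ValueError("threshold tau must be nonnegative")
    return np.abs(np.asarray(A_hat, dtype=float)) > tau


def signed_links(A_hat: NDArray[np.float64], tau: float) -> NDArray[np.int_]:
    """Signed adjacency in {-1, 0, +1}: sign of entries with ``|a_ij| > tau``."""
    A_hat = np.asarray(A_hat, dtype=float)
    return (np.sign(A_hat) * call_links(A_hat, tau)).astype(int)


def evaluate(
    predicted: NDArray, truth: NDArray
) -> tuple[ConfusionCounts, EvaluationMetrics]:
    """Confusion counts and metrics over all matrix entries.

    Boolean inputs give sign-blind scoring.  Signed integer inputs
    ({-1, 0, +1}) give sign-aware scoring: a predicted edge whose sign
    disagrees with a true edge is a false positive, and the true edge is
    not counted as missed.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    pred_called = predicted != 0
    true_edge = truth != 0
    if predicted.dtype == bool and truth.dtype == bool:
        correct = true_edge
    else:
        correct = true_edge & (np.sign(predicted) == np.sign(truth))
    tp = int(np.sum(pred_called & correct))
    fp = int(np.sum(pred_called & ~correct))
    tn = int(np.sum(~pred_called & ~true_edge))
    fn = int(np.sum(~pred_called & true_edge))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return counts, counts.metrics()
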