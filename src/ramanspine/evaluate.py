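"""Model evaluation: confusion matrices, ROC analysis, derived metrics.

Confusion matrices are oriented rows = predicted, columns = true.  ROC
curves are stored canonically as (sensitivity, specificity) pairs over a
sweep of all distinct score thresholds; the operating point is the curve
point with the shortest Euclidean distance to perfect sensitivity and
specificity.  Area under the curve (trapezoidal) is provided as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .synth import InvalidArgumentError


@dataclass
class ConfusionMatrix:
    """Integer tabulation; counts[i, j] = true class j predicted as class i."""

    counts: np.ndarray
    class_order: tuple[str, ...]
    phase: str = "testing"

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_index: int | None = None

    @property
    def operating_point(self) -> tuple[float, float]:
        i = self.operating_index
        if i is None:
            raise InvalidArgumentError("no operating point chosen yet")
        return float(self.sensitivity[i]), float(self.specificity[i])


def confusion(labels_true, labels_pred, class_order,
              phase: str = "testing") -> ConfusionMatrix:
    """Exact integer confusion tabulation (rows = predicted)."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    if labels_true.shape != labels_pred.shape:
        raise InvalidArgumentError("label arrays must have equal length")
    known = set(class_order)
    for lb in np.concatenate([labels_true, labels_pred]):
        if lb not in known:
            raise InvalidArgumentError(f"unknown label {lb!r}")
    counts = _sk_confusion(labels_true, labels_pred,
                           labels=list(class_order)).T
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order),
                           phase=phase)


def roc(scores, binary_labels) -> ROCCurve:
    """Sensitivity/specificity sweep over every distinct score threshold.

    A sample is called positive when its score is >= the threshold; the
    sweep includes one threshold above the maximum score so both curve
    endpoints (0, 1) and (1, 0-or-more) are present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("need at least one positive and one negative")
    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[-1] + 1.0], uniq[::-1]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = int(np.sum(pred & y))
        tn = int(np.sum(~pred & ~y))
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg
    # trapezoid over the (1-specificity, sensitivity) polyline
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auc=auc)


def optimal_point(curve: ROCCurve) -> tuple[float, float, float]:
    """Shortest Euclidean distance to the ideal (sens 1, spec 1) corner.

    Ties resolve toward higher sensitivity.  Returns (sensitivity,
    specificity, threshold) and records the index on the curve.
    """
    if curve.thresholds.size == 0:
        raise InvalidArgumentError("empty curve")
    d2 = (1 - curve.sensitivity) ** 2 + (1 - curve.specificity) ** 2
    best = np.flatnonzero(d2 == d2.min())
    i = int(best[np.argmax(curve.sensitivity[best])])
    curve.operating_index = i
    return (float(curve.sensitivity[i]), float(curve.specificity[i]),
            float(curve.thresholds[i]))


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class sensitivity and specificity.

    sensitivity_k = correct_k / true-count_k; specificity_k = 1 - false
    positives for k over the non-k total.  Classes absent from the truth
    get sensitivity None (undefined, not zero).
    """
    M = cm.counts
    total = M.sum()
    if total == 0:
        raise InvalidArgumentError("empty confusion matrix")
    accuracy = float(np.trace(M)) / total
    sens, spec = {}, {}
    for k, cls in enumerate(cm.class_order):
        col = M[:, k].sum()         # true count of class k
        row = M[k, :].sum()         # predicted count of class k
        sens[cls] = float(M[k, k] / col) if col > 0 else None
        denom = total - col
        spec[cls] = float(1.0 - (row - M[k, k]) / denom) if denom > 0 else None
    return {"accuracy": accuracy, "sensitivity": sens, "specificity": spec}
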