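"""Binary-classification metrics for cystic/non-cystic B-scan labels.

The positive class is the cystic state (label 1); label 2 is non-cystic.
Accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP).  Ratios with zero denominator are reported as NaN
with an explanatory flag, never silently as 0.  Scores fed to the ROC are
oriented so that larger means more cystic; AUC uses the trapezoidal rule,
which on a threshold-sweep ROC equals the rank statistic P(score_pos >
score_neg) with ties counted 1/2.

DeLong's test compares two correlated AUCs computed on the same cases via
placement values (structural components), giving a two-sided normal p-value
for the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import DegenerateError, DimensionError

__all__ = ["EvalReport", "confusion_metrics", "roc_auc", "delong_test"]


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    flags: list[str] = field(default_factory=list)
    roc: np.ndarray | None = None  # (n, 2) array of (FPR, TPR)
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "flags": list(self.flags),
        }


def _check_labels(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if not np.isin(x, (1, 2)).all():
        raise DegenerateError(f"{name} must take values in {{1, 2}}")
    return x


def confusion_metrics(pred, truth) -> EvalReport:
    """Confusion counts and the three headline ratios (cystic = positive)."""
    pred = _check_labels(pred, "pred")
    truth = _check_labels(truth, "truth")
    if pred.shape != truth.shape or pred.size == 0:
        raise DimensionError("pred and truth must be equal-length and nonempty")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 2) & (truth == 2)))
    fp = int(np.sum((pred == 1) & (truth == 2)))
    fn = int(np.sum((pred == 2) & (truth == 1)))
    flags: list[str] = []
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    if tp + fn > 0:
        sensitivity = tp / (tp + fn)
    else:
        sensitivity = float("nan")
        flags.append("sensitivity undefined: no positive cases")
    if tn + fp > 0:
        specificity = tn / (tn + fp)
    else:
        specificity = float("nan")
        flags.append("specificity undefined: no negative cases")
    return EvalReport(tp, tn, fp, fn, accuracy, sensitivity, specificity, flags)


def roc_auc(scores, truth):
    """ROC points and trapezoidal AUC for scores oriented larger = more cystic.

    Returns ``(roc_points, auc)`` where ``roc_points`` is an (n, 2) array of
    (FPR, TPR) from a sweep over the unique score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    truth = _check_labels(truth, "truth")
    if scores.shape != truth.shape:
        raise DimensionError("scores and truth must be equal-length")
    y = (truth == 1).astype(int)
    if y.min() == y.max():
        raise DegenerateError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return np.stack([fpr, tpr], axis=1), auc


def _placements(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(X, Y) = 1 if X > Y, 1/2 if equal, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01


def delong_test(scores_a, scores_b, truth):
    """DeLong's paired test for the difference of two correlated AUCs.

    Returns ``(auc_a, auc_b, z, p_value)``.  When the variance of the AUC
    difference is zero (e.g. identical score vectors) the difference is
    exactly reproducible and the test reports z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = _check_labels(truth, "truth")
    if not (scores_a.shape == scores_b.shape == truth.shape):
        raise DimensionError("paired scores and truth must be equal-length")
    y = (truth == 1).astype(int)
    if y.min() == y.max():
        raise DegenerateError("both classes must be present")
    m = int(y.sum())
    n = int((1 - y).sum())
    v10_a, v01_a = _placements(scores_a, y)
    v10_b, v01_b = _placements(scores_b, y)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)
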