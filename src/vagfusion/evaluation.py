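"""Classifier evaluation: accuracy, empirical ROC with area and standard
error, and the pooled two-sample t-test used for feature screening.

The ROC curve is the empirical (trapezoidal) one over all distinct score
thresholds, with tied scores handled by a simultaneous step; the positive
class is the abnormal (+1, diseased) one. The standard error of the area
follows Hanley & McNeil's formula with ``Q1 = A/(2-A)``,
``Q2 = 2 A^2/(1+A)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "roc_auc",
    "auc_standard_error",
    "accuracy",
    "two_sample_t_test",
]


@dataclass
class RocResult:
    """Empirical ROC curve with area under it and Hanley-McNeil SE."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    az: float
    se: float
    n_pos: int
    n_neg: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


def auc_standard_error(az: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an ROC area."""
    if not 0.0 <= az <= 1.0:
        raise ValueError("area must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be >= 1")
    q1 = az / (2.0 - az)
    q2 = 2.0 * az**2 / (1.0 + az)
    var = (
        az * (1.0 - az)
        + (n_pos - 1) * (q1 - az**2)
        + (n_neg - 1) * (q2 - az**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC curve and trapezoidal area for ±1 labels.

    Higher scores indicate the positive (+1, abnormal) class.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise ValueError("labels must be ±1")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, pos_label=1)
    az = float(np.trapezoid(tpr, fpr))
    se = auc_standard_error(az, n_pos, n_neg)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        az=az,
        se=se,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of correct predictions."""
    predictions = np.asarray(predictions).ravel()
    labels = np.asarray(labels).ravel()
    if predictions.size == 0:
        raise ValueError("accuracy undefined for empty input")
    if predictions.size != labels.size:
        raise ValueError("predictions and labels must have equal length")
    return float(np.mean(predictions == labels))


def two_sample_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance (classic Student) two-sample t-test.

    Returns ``(t, p)``. Degenerate zero-variance inputs use the limit
    conventions ``p = 1`` for equal means and ``p = 0`` otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = float(np.mean(a) - np.mean(b))
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), p
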