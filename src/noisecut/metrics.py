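"""Binary-classification metrics and median confidence intervals.

Positive class is label 1 throughout.  Undefined ratios (empty
denominators) are reported as 0.0 and flagged rather than raising, so
metric rows from degenerate test splits stay machine-readable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.metrics import confusion_matrix, roc_auc_score

__all__ = ["MetricReport", "evaluate", "median_with_ci"]


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    recall: float
    precision: float
    f1: float
    auc_roc: float
    confusion: NDArray[np.int64]  # rows: true 0/1, cols: predicted 0/1
    undefined: tuple[str, ...] = ()  # metrics zeroed for lack of a denominator

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
        }


def _safe_ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def evaluate(
    y_true: ArrayLike, y_pred: ArrayLike, scores: ArrayLike | None = None
) -> MetricReport:
    """Accuracy, recall, precision, F1 and AUC-ROC for binary labels.

    AUC is the rank statistic over ``scores`` when given; with hard labels
    only it degrades to the single-operating-point value (TPR + TNR) / 2.
    Metrics with an empty denominator are 0.0 and listed in ``undefined``
    (with a warning).
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not np.isin(y_true, (0, 1)).all() or not np.isin(y_pred, (0, 1)).all():
        raise ValueError("labels must be binary")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    (tn, fp), (fn, tp) = cm
    undefined: list[str] = []
    n = y_true.size
    accuracy = (tp + tn) / n
    recall = _safe_ratio(tp, tp + fn, "recall", undefined)
    precision = _safe_ratio(tp, tp + fp, "precision", undefined)
    if precision + recall == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if len(np.unique(y_true)) < 2:
        undefined.append("auc_roc")
        auc = 0.0
    elif scores is not None:
        auc = float(roc_auc_score(y_true, np.asarray(scores).ravel()))
    else:
        tpr = tp / (tp + fn)
        tnr = tn / (tn + fp)
        auc = (tpr + tnr) / 2
    if undefined:
        warnings.warn(
            f"metrics zeroed for empty denominators: {sorted(set(undefined))}",
            RuntimeWarning,
            stacklevel=2,
        )
    return MetricReport(
        accuracy=float(accuracy),
        recall=float(recall),
        precision=float(precision),
        f1=float(f1),
        auc_roc=float(auc),
        confusion=cm.astype(np.int64),
        undefined=tuple(sorted(set(undefined))),
    )


def median_with_ci(
    values: ArrayLike,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Sample median with a bootstrap percentile confidence interval."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("values must be non-empty")
    med = float(np.median(values))
    rng = np.random.default_rng(seed)
    boots = np.median(
        values[rng.integers(0, values.size, size=(n_boot, values.size))], axis=1
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return med, float(lo), float(hi)
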