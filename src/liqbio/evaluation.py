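"""Confusion-matrix metrics, ROC/AUC, and cross-stage macro-averages.

All ratios follow the standard definitions (accuracy, precision, recall /
sensitivity, specificity, FPR, F1, balanced accuracy = (recall +
specificity) / 2, error = 1 - accuracy).  A metric whose denominator is zero
is reported as undefined (None) rather than coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    fpr: float | None = None
    f1: float | None = None
    balanced_accuracy: float | None = None
    error: float | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Tabulate binary outcomes; 1 = positive (cancer / target class)."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape or t.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, non-empty")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(cm: ConfusionMatrix, auc: float | None = None) -> Metrics:
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = _ratio(cm.tp + cm.tn, cm.total)
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    fpr = _ratio(cm.fp, cm.fp + cm.tn)
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    balanced = (
        (recall + specificity) / 2
        if recall is not None and specificity is not None
        else None
    )
    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        fpr=fpr,
        f1=f1,
        balanced_accuracy=balanced,
        error=1.0 - accuracy if accuracy is not None else None,
        auc=auc,
    )


def roc_auc(y_true, scores) -> float | None:
    """Trapezoidal AUC over all thresholds (equals Mann-Whitney concordance); None if one class absent."""
    t = np.asarray(y_true).astype(int)
    if len(np.unique(t)) < 2:
        return None
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def roc_curve_points(y_true, scores) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs over all score thresholds, for curve export."""
    from sklearn.metrics import roc_curve as _roc_curve

    fpr, tpr, _ = _roc_curve(np.asarray(y_true).astype(int), np.asarray(scores))
    return list(zip(fpr.tolist(), tpr.tolist()))


def stage_macro_average(per_stage: list[Metrics]) -> Metrics:
    """Unweighted per-metric mean across stages, skipping undefined entries."""
    if not per_stage:
        raise ValidationError("no stage metrics to average")
    out = Metrics()
    for f in fields(Metrics):
        vals = [getattr(m, f.name) for m in per_stage if getattr(m, f.name) is not None]
        if vals:
            # fsum keeps the mean exactly invariant to stage order
            setattr(out, f.name, math.fsum(vals) / len(vals))
    return out
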