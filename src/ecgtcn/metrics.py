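"""Confusion-matrix metrics for multi-class heartbeat classification.

Per class (one-vs-rest): TP, FP, TN, FN; precision = TP / (TP + FP);
sensitivity (recall) = TP / (TP + FN).  Macro values are unweighted
means over classes.  The F-score combines the two:

    F_beta = (1 + beta^2) * S * P / (beta^2 * S + P),      F1 = F_beta(1)

The headline F1 applies the formula to the macro-averaged precision and
sensitivity; the unweighted mean of per-class F1 scores is reported
separately since published figures do not always say which convention
they use.  Classes with a zero denominator contribute 0 with a warning.

ROC curves are one-vs-rest over a threshold sweep of the predicted
class probabilities, with AUC by the trapezoid rule (delegated to
scikit-learn) and the argmax decision marked as the operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "EvaluationReport",
    "UndefinedMetricError",
    "confusion",
    "accuracy",
    "precision_sensitivity",
    "f_score",
    "roc_one_vs_rest",
    "roc",
    "evaluate",
]


class UndefinedMetricError(ValueError):
    """A metric has no defined value for the given inputs."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[actual, predicted] over a fixed label alphabet."""

    counts: np.ndarray
    labels: tuple[int, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError(f"counts shape {c.shape} does not match "
                             f"{len(self.labels)} labels")
        if (c < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, label: int) -> dict[str, int]:
        """TP/FP/TN/FN for one class against the rest."""
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Build the confusion matrix; rows are actual, columns predicted."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred])).tolist()
    else:
        labels = list(labels)
        unknown = set(np.unique(np.concatenate([y_true, y_pred])).tolist()) - set(labels)
        if y_true.size and unknown:
            raise ValueError(f"labels outside the alphabet: {sorted(unknown)}")
    if y_true.size == 0:
        return ConfusionMatrix(np.zeros((len(labels), len(labels)), dtype=np.int64),
                               tuple(labels))
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    return ConfusionMatrix(counts, tuple(labels))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined for an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


def _safe_div(num: int, den: int, what: str, label: int) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {label} "
                      "(zero denominator); using 0 by convention", stacklevel=3)
        return 0.0
    return num / den


def precision_sensitivity(cm: ConfusionMatrix
                          ) -> tuple[dict[int, float], dict[int, float], float, float]:
    """Per-class and macro precision and sensitivity.

    Returns ``(precision, sensitivity, macro_precision, macro_sensitivity)``;
    zero-denominator classes contribute 0 with a warning.
    """
    if cm.total == 0:
        raise UndefinedMetricError("metrics undefined for an empty matrix")
    precision, sensitivity = {}, {}
    for label in cm.labels:
        q = cm.one_vs_rest(label)
        precision[label] = _safe_div(q["TP"], q["TP"] + q["FP"], "precision", label)
        sensitivity[label] = _safe_div(q["TP"], q["TP"] + q["FN"], "sensitivity", label)
    macro_p = float(np.mean(list(precision.values())))
    macro_s = float(np.mean(list(sensitivity.values())))
    return precision, sensitivity, macro_p, macro_s


def f_score(precision: float, sensitivity: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean of precision and sensitivity; F1 at beta=1."""
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    if not (0.0 <= precision <= 1.0 and 0.0 <= sensitivity <= 1.0):
        raise ValueError("precision and sensitivity must lie in [0, 1]")
    den = beta ** 2 * sensitivity + precision
    if den == 0.0:
        return 0.0
    return (1.0 + beta ** 2) * sensitivity * precision / den


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    operating_point: tuple[float, float]  # (FPR, TPR) of the argmax decision


def roc_one_vs_rest(y_true, scores, positive_label: int,
                    y_pred=None) -> RocCurve:
    """One-vs-rest ROC for one class from its probability scores.

    ``scores`` holds the predicted probability of ``positive_label`` per
    sample.  Raises :class:`UndefinedMetricError` when the truth vector
    contains only one class.  When ``y_pred`` is given, the operating
    point is the (FPR, TPR) realised by that hard decision.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == positive_label
    if pos.all() or not pos.any():
        raise UndefinedMetricError(
            f"AUC undefined for class {positive_label}: single-class truth")
    fpr, tpr, thr = _sk_roc_curve(pos.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    op = (np.nan, np.nan)
    if y_pred is not None:
        y_pred = np.asarray(y_pred)
        pred_pos = y_pred == positive_label
        tp = int((pred_pos & pos).sum())
        fp = int((pred_pos & ~pos).sum())
        op = (fp / max(int((~pos).sum()), 1), tp / max(int(pos.sum()), 1))
    return RocCurve(fpr, tpr, thr, auc, op)


def roc(y_true, class_scores: np.ndarray, labels=None,
        y_pred=None) -> dict[int, RocCurve]:
    """Per-class one-vs-rest ROC curves from an (n, n_classes) score matrix.

    Classes with single-class truth get no entry (a warning is emitted).
    """
    y_true = np.asarray(y_true)
    class_scores = np.asarray(class_scores, dtype=np.float64)
    if labels is None:
        labels = np.unique(y_true).tolist()
    labels = list(labels)
    if class_scores.shape != (y_true.size, len(labels)):
        raise ValueError(f"scores shape {class_scores.shape} does not match "
                         f"({y_true.size}, {len(labels)})")
    if y_pred is None:
        y_pred = np.asarray(labels)[np.argmax(class_scores, axis=1)]
    curves = {}
    for j, label in enumerate(labels):
        try:
            curves[label] = roc_one_vs_rest(y_true, class_scores[:, j], label,
                                            y_pred=y_pred)
        except UndefinedMetricError as e:
            warnings.warn(str(e), stacklevel=2)
    return curves


@dataclass(frozen=True)
class EvaluationReport:
    """Everything derived from one set of predictions."""

    cm: ConfusionMatrix
    accuracy: float
    precision: dict[int, float]
    sensitivity: dict[int, float]
    macro_precision: float
    macro_sensitivity: float
    f1_of_macros: float       # F1 applied to macro precision/sensitivity (headline)
    macro_of_f1s: float       # unweighted mean of per-class F1 scores
    beta: float
    f_beta: float
    roc_curves: dict[int, RocCurve] = field(default_factory=dict)

    def summary(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "f1_of_macros": self.f1_of_macros,
            "macro_of_f1s": self.macro_of_f1s,
            f"f_beta(beta={self.beta:g})": self.f_beta,
        }
        for label, curve in self.roc_curves.items():
            d[f"auc_class_{label}"] = curve.auc
        return d


def evaluate(y_true, y_pred, class_scores=None, labels=None,
             beta: float = 1.0) -> EvaluationReport:
    """Full evaluation: confusion matrix, accuracy, P/S, F-scores, ROC."""
    cm = confusion(y_true, y_pred, labels=labels)
    acc = accuracy(cm)
    prec, sens, macro_p, macro_s = precision_sensitivity(cm)
    per_class_f1 = [f_score(prec[l], sens[l], 1.0) for l in cm.labels]
    curves = {}
    if class_scores is not None:
        curves = roc(y_true, class_scores, labels=list(cm.labels), y_pred=y_pred)
    return EvaluationReport(
        cm=cm, accuracy=acc, precision=prec, sensitivity=sens,
        macro_precision=macro_p, macro_sensitivity=macro_s,
        f1_of_macros=f_score(macro_p, macro_s, 1.0),
        macro_of_f1s=float(np.mean(per_class_f1)),
        beta=beta, f_beta=f_score(macro_p, macro_s, beta),
        roc_curves=curves)
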