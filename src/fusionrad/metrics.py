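"""Binary-classification evaluation metrics.

Implements the evaluation quantities used throughout the package: the
confusion table, precision / recall / F-alpha, sensitivity / specificity /
accuracy, the all-points precision-recall curve with its average precision
(AP) and mean AP, and the ROC curve with trapezoidal AUC.  The positive
class is always *malignant* (label 1).

Conventions for degenerate counts (0/0): precision (or recall) is defined
as 0 when its denominator is 0, and F-alpha is 0 when P + R = 0; such
reports carry a ``degenerate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "prf",
    "sensitivity_specificity_accuracy",
    "pr_curve_and_ap",
    "mean_average_precision",
    "roc_auc",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts with malignant (1) as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    """Scalar metrics plus PR/ROC curve points for one evaluation."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    auc: float = float("nan")
    ap: float = float("nan")
    pr_curve: tuple[np.ndarray, np.ndarray] | None = None
    roc_curve: tuple[np.ndarray, np.ndarray] | None = None
    degenerate: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "ap": self.ap,
            "degenerate": list(self.degenerate),
        }


def _validate_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1 (1 = malignant/positive)")
    return labels.astype(int)


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/FP/FN/TN for binary labels and hard predictions."""
    y = _validate_binary(labels)
    p = _validate_binary(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def prf(counts: ConfusionCounts, alpha: float = 1.0) -> tuple[float, float, float]:
    """Precision, recall and the weighted F-measure.

    F_alpha = (alpha^2 + 1) P R / (alpha^2 P + R); alpha = 1 gives the
    harmonic mean 2PR/(P+R).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    denom = alpha**2 * p + r
    f = (alpha**2 + 1) * p * r / denom if denom > 0 else 0.0
    return p, r, f


def sensitivity_specificity_accuracy(counts: ConfusionCounts) -> tuple[float, float, float]:
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else 0.0
    acc = (counts.tp + counts.tn) / counts.n if counts.n else 0.0
    return sens, spec, acc


def pr_curve_and_ap(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """All-points precision-recall curve and its average precision.

    The curve is swept over every distinct score threshold (descending).
    AP is the area under the precision *envelope* (all-points
    interpolation: at recall R the envelope is the maximum precision
    achieved at any recall >= R), integrated over the recall increments.

    Returns ``(recall, precision, ap)``; raises if only one class present.
    """
    y = _validate_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("AP undefined: labels contain a single class")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last entry of each tied-score block
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp, fp = tp[distinct], fp[distinct]
    recall = tp / n_pos
    precision = tp / (tp + fp)
    # precision envelope, right-to-left running max
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.r_[0.0, recall[:-1]]
    ap = float(np.sum((recall - prev_recall) * envelope))
    return recall, precision, ap


def mean_average_precision(per_class_aps) -> float:
    """Arithmetic mean of per-class average precisions."""
    aps = np.asarray(per_class_aps, dtype=float)
    if aps.size == 0:
        raise ValueError("need at least one per-class AP")
    return float(aps.mean())


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over distinct thresholds) and trapezoidal AUC.

    Tied scores are collapsed into a single threshold step, which makes
    the trapezoidal area equal the rank-averaged Mann-Whitney U statistic
    normalized by n_pos * n_neg.
    """
    y = _validate_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_scores(labels, scores, threshold: float = 0.0, alpha: float = 1.0) -> EvalReport:
    """Full report from continuous scores: threshold for the hard metrics,
    plus AP and AUC from the ranking."""
    y = _validate_binary(labels)
    s = np.asarray(scores, dtype=float)
    counts = confusion(y, (s > threshold).astype(int))
    p, r, f = prf(counts, alpha=alpha)
    sens, spec, acc = sensitivity_specificity_accuracy(counts)
    degenerate = []
    if counts.tp + counts.fp == 0:
        degenerate.append("precision")
    if counts.tp + counts.fn == 0:
        degenerate.append("recall")
    recall_c, precision_c, ap = pr_curve_and_ap(s, y)
    fpr, tpr, auc = roc_auc(s, y)
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        precision=p,
        accuracy=acc,
        f1=f,
        auc=auc,
        ap=ap,
        pr_curve=(recall_c, precision_c),
        roc_curve=(fpr, tpr),
        degenerate=degenerate,
    )
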