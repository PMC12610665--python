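"""Evaluation metrics computed from confusion matrices and score rankings.

All threshold metrics (accuracy, precision, recall, f1, Cohen's kappa and the
per-class recalls) are derived directly from the confusion matrix; ranking
metrics (AUC-ROC by the trapezoidal rule over the ROC sweep, average precision
by step-wise precision-recall summation, and one-vs-rest mAP) are computed
from per-sample scores.  Multiclass threshold metrics are one-vs-rest with
macro averaging by default.

Conventions for degenerate cases: a per-class ratio with a zero denominator is
reported as 0 and a warning is emitted, so a pathological cross-validation
fold never crashes the evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "classification_metrics",
    "roc_auc",
    "average_precision",
    "map_multiclass",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix indexed (actual, predicted) over ``label_set``."""

    counts: np.ndarray
    label_set: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.label_set)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over label_set")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """Metric family derived from one evaluation."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    per_class_recall: dict[str, float] = field(default_factory=dict)
    auc_roc: float | None = None
    ap_or_map: float | None = None
    positive_class: str | None = None
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_matrix(actual, predicted, label_set) -> ConfusionMatrix:
    """Count matrix with rows = actual class, columns = predicted class."""
    actual = [str(a) for a in actual]
    predicted = [str(p) for p in predicted]
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    label_set = tuple(str(l) for l in label_set)
    index = {lab: i for i, lab in enumerate(label_set)}
    k = len(label_set)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise ValueError(f"label outside label_set: {a!r} / {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, label_set)


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", RuntimeWarning)
        return 0.0
    return num / den


def _kappa(cm: np.ndarray) -> float:
    n = cm.sum()
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum()) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def classification_metrics(
    cm: ConfusionMatrix,
    positive_class: str | None = None,
    averaging: str = "macro",
) -> EvalReport:
    """Accuracy, precision, recall, f1, kappa and per-class recalls.

    With ``positive_class`` given (binary problems), precision/recall/f1 refer
    to that class.  Otherwise each class is treated as positive in turn
    (one-vs-rest) and the per-class values are combined by macro (unweighted)
    or weighted (by class support) averaging.
    """
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    labels = cm.label_set
    accuracy = np.trace(counts) / counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    diag = np.diag(counts)
    per_prec = np.array(
        [_safe_ratio(diag[i], col[i], f"precision[{labels[i]}]") for i in range(len(labels))]
    )
    per_rec = np.array(
        [_safe_ratio(diag[i], row[i], f"recall[{labels[i]}]") for i in range(len(labels))]
    )
    per_f1 = np.array(
        [
            _safe_ratio(2 * p * r, p + r, f"f1[{labels[i]}]")
            for i, (p, r) in enumerate(zip(per_prec, per_rec))
        ]
    )
    per_class_recall = {lab: float(r) for lab, r in zip(labels, per_rec)}

    if positive_class is not None:
        if positive_class not in labels:
            raise ValueError(f"positive_class {positive_class!r} not in label_set")
        i = labels.index(positive_class)
        precision, recall, f1 = per_prec[i], per_rec[i], per_f1[i]
    elif averaging == "macro":
        precision, recall, f1 = per_prec.mean(), per_rec.mean(), per_f1.mean()
    else:
        wts = row / row.sum()
        precision, recall, f1 = (per_prec * wts).sum(), (per_rec * wts).sum(), (per_f1 * wts).sum()

    return EvalReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        kappa=float(_kappa(counts)),
        per_class_recall=per_class_recall,
        positive_class=positive_class,
        averaging=averaging,
    )


def _binary_targets(actual, positive_label) -> np.ndarray:
    actual = np.asarray(actual)
    uniq = np.unique(actual)
    if uniq.size < 2:
        raise ValueError("need both classes present to evaluate a ranking metric")
    if uniq.size > 2:
        raise ValueError("binary ranking metric on a multiclass label vector")
    if positive_label is None:
        positive_label = uniq[-1]
    return (actual == positive_label).astype(int)


def roc_auc(scores, actual, positive_label=None) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    The TPR/FPR curve is swept over every distinct score threshold (tied
    scores are grouped at one threshold) and integrated with trapezoids; this
    equals the Mann-Whitney concordance statistic.
    """
    scores = np.asarray(scores, dtype=np.float64)
    t = _binary_targets(actual, positive_label)
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], t[order]
    # cumulative TP/FP after each group of tied scores
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(t)[distinct]
    fp = np.cumsum(1 - t)[distinct]
    P, N = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    return float(np.sum((fpr[1:] - fpr[:-1]) * (tpr[1:] + tpr[:-1]) / 2.0))


def average_precision(scores, actual, positive_label=None) -> float:
    """Step-wise precision-recall summation: AP = sum_k P(k) * dR(k)."""
    scores = np.asarray(scores, dtype=np.float64)
    t = _binary_targets(actual, positive_label)
    if t.sum() == 0:
        raise ValueError("no positive samples")
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], t[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(t)[distinct]
    fp = np.cumsum(1 - t)[distinct]
    precision = tp / (tp + fp)
    recall = tp / t.sum()
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drecall))


def map_multiclass(scores: np.ndarray, actual, label_set) -> float:
    """Mean one-vs-rest average precision over the classes.

    ``scores`` is (n_samples, n_classes) with columns ordered by
    ``label_set``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    actual = np.asarray(actual)
    label_set = tuple(label_set)
    if scores.shape[1] != len(label_set):
        raise ValueError("scores columns must match label_set")
    aps = []
    for j, lab in enumerate(label_set):
        t = (actual == lab).astype(int)
        if t.sum() == 0:
            raise ValueError(f"no positive samples for class {lab!r}")
        aps.append(average_precision(scores[:, j], t, positive_label=1))
    return float(np.mean(aps))
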