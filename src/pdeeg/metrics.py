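"""Confusion-matrix metrics and ROC/AUC.

Accuracy, precision, recall (sensitivity), specificity and F1 follow the
standard contingency formulas; undefined ratios (zero denominators) are
reported as 0.0 with a flag rather than raising.  AUC uses the
rank-statistic (Mann-Whitney) formulation with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))))


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    confusion: ConfusionMatrix
    auc: float | None = None
    per_class: dict = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "specificity": self.specificity,
             "f1": self.f1,
             "confusion": {"tp": self.confusion.tp, "tn": self.confusion.tn,
                           "fp": self.confusion.fp, "fn": self.confusion.fn}}
        if self.auc is not None:
            d["auc"] = self.auc
        if self.per_class:
            d["per_class"] = self.per_class
        if self.undefined:
            d["undefined"] = list(self.undefined)
        return d


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def _one_class(cm: ConfusionMatrix, undefined: list[str]) -> dict:
    acc = (cm.tp + cm.tn) / cm.total
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision", undefined)
    rec = _ratio(cm.tp, cm.tp + cm.fn, "recall", undefined)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    if (prec + rec) == 0:
        undefined.append("f1")
    return {"accuracy": acc, "precision": prec, "recall": rec,
            "specificity": spec, "f1": f1}


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, specificity and F1 from a contingency.

    The per-class breakdown reports the same metrics with each class in
    turn treated as positive (PD = class 1, control = class 0 with the
    contingency's roles swapped).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    pd_metrics = _one_class(cm, undefined)
    control_cm = ConfusionMatrix(tp=cm.tn, tn=cm.tp, fp=cm.fn, fn=cm.fp)
    control_metrics = _one_class(control_cm, [])
    return MetricsReport(accuracy=pd_metrics["accuracy"],
                         precision=pd_metrics["precision"],
                         recall=pd_metrics["recall"],
                         specificity=pd_metrics["specificity"],
                         f1=pd_metrics["f1"], confusion=cm,
                         per_class={"pd": pd_metrics, "control": control_metrics},
                         undefined=undefined)


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC by the rank formulation (ties half) plus ROC curve points.

    Returns (auc, fpr, tpr) with curve points at every distinct threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties at half weight
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return float(auc), fpr, tpr
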