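"""Classifier evaluation: confusion-matrix metrics, AUROC, macro-F1.

Two evaluation tasks mirror how a physiotherapy tracker is validated:
binary (any exercise vs activities of daily living) and multiclass
(which exercise). Rates come from the confusion matrix; AUROC from
positive-class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score, roc_auc_score


@dataclass
class ClassifierMetrics:
    accuracy: float
    sensitivity: float | None = None   # binary: TP / (TP + FN)
    specificity: float | None = None   # binary: TN / (TN + FP)
    auroc: float | None = None         # binary only
    macro_f1: float | None = None      # multiclass: unweighted mean per-class F1
    confusion_matrix: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    labels: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy}
        for k in ("sensitivity", "specificity", "auroc", "macro_f1"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        d["confusion_matrix"] = self.confusion_matrix.tolist()
        d["labels"] = np.asarray(self.labels).tolist()
        return d


def binarize_labels(y: np.ndarray, exercise_ids) -> np.ndarray:
    """Collapse class ids to 1 (any exercise) / 0 (daily living)."""
    ex = set(int(i) for i in exercise_ids)
    return np.array([1 if int(v) in ex else 0 for v in np.asarray(y)])


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    task: str,
    proba_positive: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> ClassifierMetrics:
    """Score predictions on a labeled test set.

    ``task`` is ``"binary"`` (labels 0/1, sensitivity/specificity/AUROC)
    or ``"multiclass"`` (accuracy and macro-F1). ``proba_positive`` is
    the positive-class probability per window, required for AUROC.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    if task not in ("binary", "multiclass"):
        raise ValueError(f"unknown task {task!r}")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    acc = float(np.trace(cm) / cm.sum())
    if task == "binary":
        if not set(np.unique(y_true)) <= {0, 1}:
            raise ValueError("binary task expects labels in {0, 1}")
        cm = _sk_confusion(y_true, y_pred, labels=[0, 1])
        tn, fp, fn, tp = cm.ravel()
        sens = tp / (tp + fn) if (tp + fn) else float("nan")
        spec = tn / (tn + fp) if (tn + fp) else float("nan")
        auroc = None
        if proba_positive is not None and len(np.unique(y_true)) == 2:
            auroc = float(roc_auc_score(y_true, proba_positive))
        return ClassifierMetrics(acc, float(sens), float(spec), auroc,
                                 None, cm, np.array([0, 1]))
    macro = float(f1_score(y_true, y_pred, labels=labels,
                           average="macro", zero_division=0))
    return ClassifierMetrics(acc, None, None, None, macro, cm,
                             np.asarray(labels))
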