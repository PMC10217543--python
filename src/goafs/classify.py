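"""Classifier training/evaluation and the confusion-matrix metric panel.

The diagnostic indices are the standard percentage-scale formulas:

    Acc         = (TP + TN) / (TP + TN + FP + FN) * 100
    Recall      = TP / (TP + FN) * 100          (sensitivity)
    Precision   = TP / (TP + FP) * 100
    F1          = 2 * Recall * Precision / (Recall + Precision)
    Specificity = TN / (TN + FP) * 100

The positive class defaults to the cancerous label (1, matching the
``colon_aca`` folder in the LC25000 layout).  A metric whose
denominator is zero raises rather than returning a sentinel, so a
degenerate evaluation can never masquerade as a score.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .synthetic import FeatureTable

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "UndefinedMetricError",
    "confusion",
    "metrics",
    "train_eval",
    "make_classifier",
    "CLASSIFIERS",
]

CLASSIFIERS = ("svm", "decision_tree")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for this confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """The five diagnostic indices, as percentages in [0, 100]."""

    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(
    true_labels,
    predicted_labels,
    positive_class=1,
) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix with a declared positive class."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("true and predicted labels must be equal-length vectors")
    labels = set(np.unique(y)) | set(np.unique(p))
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(labels)}")
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    pos_true = y == positive_class
    pos_pred = p == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_true & pos_pred)),
        tn=int(np.sum(~pos_true & ~pos_pred)),
        fp=int(np.sum(~pos_true & pos_pred)),
        fn=int(np.sum(pos_true & ~pos_pred)),
    )


def metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Compute the five-index panel from a confusion matrix.

    Raises :class:`UndefinedMetricError` naming the first metric whose
    denominator is zero.
    """
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty confusion matrix")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            raise UndefinedMetricError(f"{name} undefined: zero denominator")
        return 100.0 * num / den

    acc = ratio(cm.tp + cm.tn, cm.total, "accuracy")
    recall = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    specificity = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    if recall + precision == 0:
        raise UndefinedMetricError("f1 undefined: recall + precision is zero")
    f1 = 2.0 * recall * precision / (recall + precision)
    return ClassificationMetrics(
        sensitivity=recall,
        specificity=specificity,
        accuracy=acc,
        precision=precision,
        f1=f1,
    )


def make_classifier(classifier_id: str, seed: int = 0):
    """Instantiate a classifier by id: RBF-kernel SVM or decision tree."""
    if classifier_id == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if classifier_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(
        f"unknown classifier {classifier_id!r}; choose from {CLASSIFIERS}"
    )


def train_eval(
    table: FeatureTable,
    mask=None,
    classifier_id: str = "svm",
    n_splits: int = 5,
    seed: int = 0,
    positive_class=1,
) -> tuple[ClassificationMetrics, ConfusionMatrix]:
    """Cross-validated evaluation on the masked columns of a table.

    Stratified ``n_splits``-fold CV; the held-out predictions of all
    folds are pooled into a single confusion matrix so the counts sum
    to the table's row count.  Seeded fold shuffling makes the result
    reproducible.
    """
    if len(table.classes()) < 2:
        raise ValueError("table must contain both classes")
    X = table.values
    if mask is not None:
        bits = np.asarray(getattr(mask, "bits", mask), dtype=bool)
        if bits.shape != (table.n_features,):
            raise ValueError("mask length must equal the table's feature count")
        if not bits.any():
            raise ValueError("mask selects zero features")
        X = X[:, bits]
    y = np.asarray(table.labels)

    predictions = np.empty_like(y)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                "a training fold contains a single class; "
                "use stratification or a larger sample"
            )
        clf = make_classifier(classifier_id, seed)
        clf.fit(X[train_idx], y[train_idx])
        predictions[test_idx] = clf.predict(X[test_idx])

    cm = confusion(y, predictions, positive_class=positive_class)
    return metrics(cm), cm
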