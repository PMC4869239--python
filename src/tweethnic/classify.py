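"""RBF-kernel timeline classification and its evaluation metrics.

The classifier is a support vector machine with a radial basis function
kernel over either bag-of-words or topic-simplex timeline
representations.  Evaluation follows the imbalanced-multiclass
conventions of the method: a pooled ten-fold cross-validated confusion
matrix (rows = predicted class, columns = reference class), per-class
one-vs-rest *balanced accuracy* ``100 * (sensitivity + specificity) / 2``,
*overall accuracy* ``100 * trace / total``, and *pair accuracy* (overall
accuracy of the sub-matrix restricted to a chosen class subset, e.g. the
two majority groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .corpus import EthnicityLabel, Group, Provenance

__all__ = [
    "ClassifierConfig",
    "TimelineEthnicityClassifier",
    "ConfusionMatrix",
    "EvaluationReport",
    "crossvalidate",
    "balanced_accuracy",
    "overall_accuracy",
    "pair_accuracy",
    "evaluation_report",
    "predict_unlabeled",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM hyperparameters (kernel is fixed to RBF)."""

    C: float = 1.0
    gamma: float | str = "scale"
    class_weighting: str = "none"  # "none" | "inverse_frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.class_weighting not in ("none", "inverse_frequency"):
            raise ValueError("class_weighting: none | inverse_frequency")


class TimelineEthnicityClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM over timeline representations (sklearn estimator).

    No class weighting is applied by default: on imbalanced training
    data the decision function then over-predicts the majority classes,
    which is the documented behaviour of the method this package
    implements; ``class_weighting="inverse_frequency"`` enables
    sklearn's balanced reweighting.
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma: float | str = "scale",
        class_weighting: str = "none",
        seed: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.class_weighting = class_weighting
        self.seed = seed

    def fit(self, X, y):
        ClassifierConfig(self.C, self.gamma, self.class_weighting, self.seed)
        y = np.asarray(
            [g.value if isinstance(g, Group) else str(g) for g in y]
        )
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to fit")
        weight = (
            "balanced" if self.class_weighting == "inverse_frequency" else None
        )
        self._svc_ = SVC(
            kernel="rbf",
            C=self.C,
            gamma=self.gamma,
            class_weight=weight,
            random_state=self.seed,
        )
        self._svc_.fit(X, y)
        self.classes_ = self._svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_svc_")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"representation has {X.shape[1]} features, model expects "
                f"{self.n_features_in_} — rebuild with the training "
                "vocabulary/topic model"
            )
        return self._svc_.predict(X)


@dataclass
class ConfusionMatrix:
    """Prediction-vs-reference counts: rows = predicted, cols = reference."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.classes = tuple(
            c.value if isinstance(c, Group) else str(c) for c in self.classes
        )
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square in the class count")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _idx(self, cls) -> int:
        name = cls.value if isinstance(cls, Group) else str(cls)
        return self.classes.index(name)

    def reference_total(self, cls) -> int:
        return int(self.counts[:, self._idx(cls)].sum())

    def restrict(self, subset: Sequence) -> "ConfusionMatrix":
        idx = [self._idx(c) for c in subset]
        return ConfusionMatrix(
            counts=self.counts[np.ix_(idx, idx)],
            classes=tuple(self.classes[i] for i in idx),
        )


def crossvalidate(
    X,
    y: Sequence,
    folds: int = 10,
    config: ClassifierConfig | None = None,
    stratified: bool = False,
) -> ConfusionMatrix:
    """Pooled k-fold cross-validated confusion matrix.

    The labeled set is split into *folds* seeded random bins whose sizes
    differ by at most one; each bin is predicted once by a model trained
    on the other bins, and the confusion matrix pools all folds.  Folds
    are non-stratified by default; if a class is missing from some
    training split the error advises ``stratified=True``.
    """
    if config is None:
        config = ClassifierConfig()
    y = np.asarray([g.value if isinstance(g, Group) else str(g) for g in y])
    n = len(y)
    if n < folds:
        raise ValueError(f"need >= {folds} labeled examples")
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=folds, shuffle=True, random_state=config.seed)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    cls_idx = {c: i for i, c in enumerate(classes)}
    X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
    for train, test in splitter.split(np.zeros(n), y):
        if set(classes) - set(y[train]):
            missing = sorted(set(classes) - set(y[train]))
            raise ValueError(
                f"class(es) {missing} absent from a training split; "
                "re-run with stratified=True"
            )
        model = TimelineEthnicityClassifier(
            C=config.C,
            gamma=config.gamma,
            class_weighting=config.class_weighting,
            seed=config.seed,
        ).fit(X[train], y[train])
        pred = model.predict(X[test])
        for p, r in zip(pred, y[test]):
            cm[cls_idx[p], cls_idx[r]] += 1
    return ConfusionMatrix(counts=cm, classes=classes)


def balanced_accuracy(cm: ConfusionMatrix, cls) -> float:
    """One-vs-rest balanced accuracy for one class, in percent.

    ``100 * (sensitivity + specificity) / 2`` where sensitivity is the
    fraction of the class's reference members predicted as the class and
    specificity the fraction of non-members not predicted as the class.
    """
    i = cm._idx(cls)
    ref_pos = cm.counts[:, i].sum()
    if ref_pos == 0:
        raise ZeroDivisionError(
            f"class {cm.classes[i]!r} has no reference members"
        )
    tp = cm.counts[i, i]
    ref_neg = cm.total - ref_pos
    fp = cm.counts[i, :].sum() - tp  # non-members predicted as the class
    sensitivity = tp / ref_pos
    specificity = (ref_neg - fp) / ref_neg if ref_neg else 1.0
    return 100.0 * (sensitivity + specificity) / 2.0


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """``100 * trace / total`` over the full matrix."""
    if cm.total == 0:
        raise ZeroDivisionError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.total


def pair_accuracy(cm: ConfusionMatrix, subset: Sequence) -> float:
    """Overall accuracy restricted to reference AND prediction in *subset*."""
    if not list(subset):
        raise ValueError("class subset must be non-empty")
    return overall_accuracy(cm.restrict(subset))


@dataclass
class EvaluationReport:
    balanced: dict[str, float]
    overall: float
    pair: float | None
    pair_classes: tuple[str, ...] | None
    confusion: ConfusionMatrix


def evaluation_report(
    cm: ConfusionMatrix,
    pair_classes: Sequence | None = (Group.CAUCASIAN, Group.AFRICAN_AMERICAN),
) -> EvaluationReport:
    """Bundle the per-class balanced accuracies, overall accuracy and the
    two-majority-group pair accuracy for one confusion matrix."""
    balanced = {
        c: balanced_accuracy(cm, c)
        for c in cm.classes
        if cm.reference_total(c) > 0
    }
    pair = None
    names = None
    if pair_classes is not None:
        names = tuple(
            c.value if isinstance(c, Group) else str(c) for c in pair_classes
        )
        if all(n in cm.classes for n in names):
            pair = pair_accuracy(cm, names)
    return EvaluationReport(
        balanced=balanced,
        overall=overall_accuracy(cm),
        pair=pair,
        pair_classes=names,
        confusion=cm,
    )


def predict_unlabeled(
    model: TimelineEthnicityClassifier,
    X,
    user_ids: Sequence[str],
) -> dict[str, EthnicityLabel]:
    """Predict a group for every unlabeled user (no abstention)."""
    pred = model.predict(X)
    return {
        uid: EthnicityLabel(Group(p), Provenance.PREDICTED)
        for uid, p in zip(user_ids, pred)
    }
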