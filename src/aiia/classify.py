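"""Cross-validated classification of gram-feature records.

Records are classified from their gram-probability vectors under k-fold
cross-validation (default 10 folds, stratified).  Fold predictions are
pooled into one confusion matrix, from which overall accuracy
(correct / total) and per-class accuracy (diagonal / row sum) follow —
the same arithmetic as a "correctly classified instances" tally.

The classifier interface is pluggable (any scikit-learn style
``fit``/``predict`` estimator).  The repository's fully specified
reference classifier is a Gaussian naive Bayes with a variance floor; the
registry additionally maps the six conventional classifier names to
scikit-learn estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

from .errors import (
    DegenerateModelError,
    ParameterError,
    UndefinedClassError,
)

__all__ = [
    "CVConfig",
    "CVReport",
    "make_folds",
    "crossvalidate",
    "per_class_accuracy",
    "format_accuracy",
    "GaussianNBClassifier",
    "make_classifier",
    "CLASSIFIER_REGISTRY",
]


def format_accuracy(fraction: float) -> str:
    """Render an accuracy fraction as a percentage, one decimal, half-up.

    126/142 -> '88.7%', 7/9 -> '77.8%', 19/20 -> '95.0%'.
    """
    pct = Decimal(repr(float(fraction) * 100)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{pct}%"


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings."""

    folds: int = 10
    stratified: bool = True
    seed: int = 0
    classifier_name: str = "reference_gnb"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ParameterError(f"folds must be >= 2, got {self.folds}")


@dataclass(frozen=True)
class CVReport:
    """Pooled-over-folds confusion matrix and the accuracies derived from it.

    Invariants: the confusion entries sum to ``n_total``; the trace is
    ``n_correct``; ``overall_accuracy = n_correct / n_total``; each class's
    accuracy is its diagonal entry over its row sum.
    """

    classes: Tuple[str, ...]
    confusion: np.ndarray
    per_fold_accuracy: Tuple[float, ...]

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def n_incorrect(self) -> int:
        return self.n_total - self.n_correct

    @property
    def overall_accuracy(self) -> float:
        return self.n_correct / self.n_total

    @property
    def per_class_accuracy(self) -> Dict[str, float]:
        return per_class_accuracy(self)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": {
                c: {d: int(self.confusion[i, j]) for j, d in enumerate(self.classes)}
                for i, c in enumerate(self.classes)
            },
            "per_fold_accuracy": list(self.per_fold_accuracy),
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        """Human-readable summary in the layout of a results table."""
        lines = [
            f"Total instances      {self.n_total}",
            f"Correctly classified {self.n_correct}",
            f"Incorrectly classified {self.n_incorrect}",
            f"Accuracy             {format_accuracy(self.overall_accuracy)}",
            "",
            "Group     " + "".join(f"{c:>8}" for c in self.classes),
            "Total     "
            + "".join(f"{int(r):>8}" for r in self.confusion.sum(axis=1)),
            "Correct   "
            + "".join(f"{int(self.confusion[i, i]):>8}" for i in range(len(self.classes))),
            "Accuracy  "
            + "".join(
                f"{format_accuracy(a):>8}"
                for a in self.per_class_accuracy.values()
            ),
        ]
        return "\n".join(lines)


def per_class_accuracy(report: CVReport) -> Dict[str, float]:
    """Diagonal over row sum, per class; rows must be non-empty."""
    out = {}
    for i, c in enumerate(report.classes):
        row = report.confusion[i].sum()
        if row == 0:
            raise UndefinedClassError(f"class {c!r} has no instances")
        out[c] = float(report.confusion[i, i] / row)
    return out


def make_folds(
    labels: Sequence[str], config: CVConfig
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Partition record indices into train/validation folds.

    Validation sets are disjoint and exhaustive — every record is validated
    exactly once.  Stratified folds preserve class proportions to within
    one member per class per fold.  Deterministic given ``config.seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if config.folds > n:
        raise ParameterError(
            f"folds={config.folds} exceeds number of records {n}"
        )
    counts = np.unique(labels, return_counts=True)[1]
    if config.stratified and np.any(counts >= config.folds):
        splitter = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed
        )
    else:
        # Stratification is undefined when every class is smaller than the
        # fold count (e.g. the leave-one-out limit); fall back to plain
        # shuffled folds, which still partition the indices exactly.
        splitter = KFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed
        )
    import warnings

    with warnings.catch_warnings():
        # A class smaller than the fold count (e.g. 9 AF records under 10
        # folds) is part of the study design: some folds simply hold no
        # validation member of that class.
        warnings.filterwarnings(
            "ignore", message="The least populated class", category=UserWarning
        )
        return [
            (train, val) for train, val in splitter.split(np.zeros(n), labels)
        ]


def crossvalidate(
    features,
    labels: Sequence[str],
    classifier: BaseEstimator,
    config: Optional[CVConfig] = None,
) -> CVReport:
    """k-fold cross-validation pooling fold predictions into one confusion.

    Parameters
    ----------
    features : ndarray (n_records, n_features) or sklearn-transformable input
        Feature matrix, or — when ``classifier`` is a Pipeline containing
        the symbolization step — the raw per-record inputs.  Passing the
        raw inputs through a pipeline ensures that under pooled
        symbolization the symbol model is refitted inside each fold on
        training records only (no leakage).
    labels : sequence of class names
    classifier : estimator with fit/predict
        Cloned fresh for every fold.
    config : CVConfig

    Returns
    -------
    CVReport
    """
    config = config or CVConfig()
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))

    def take(idx):
        if isinstance(features, np.ndarray):
            return features[idx]
        return [features[i] for i in idx]

    folds = make_folds(labels, config)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    for fold_i, (train, val) in enumerate(folds):
        est = clone(classifier)
        try:
            est.fit(take(train), labels[train])
            pred = np.asarray(est.predict(take(val)))
        except Exception as exc:  # surface the failing fold
            raise RuntimeError(
                f"classifier failed on fold {fold_i}: {exc}"
            ) from exc
        confusion += _sk_confusion(labels[val], pred, labels=classes)
        fold_acc.append(float(np.mean(pred == labels[val])))
    return CVReport(
        classes=classes,
        confusion=confusion,
        per_fold_accuracy=tuple(fold_acc),
    )


class GaussianNBClassifier(BaseEstimator, ClassifierMixin):
    """Reference Gaussian naive Bayes classifier.

    Per-class prior = class frequency; each feature gets a class-conditional
    Gaussian whose variance is floored at ``var_floor_ratio`` times the
    largest per-feature variance of the training data (so constant features
    never produce a zero variance).  Prediction is the argmax of
    log-prior + sum of log densities.  Fully deterministic.

    This is the repository's one fully specified classifier; heavier
    classifiers plug in through the same fit/predict interface.
    """

    def __init__(self, var_floor_ratio: float = 1e-9):
        self.var_floor_ratio = var_floor_ratio

    def fit(self, X, y) -> "GaussianNBClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(y.tolist())))
        if self.classes_.size < 2:
            raise DegenerateModelError(
                "training data contains a single class"
            )
        n, p = X.shape
        self.theta_ = np.zeros((self.classes_.size, p))
        self.var_ = np.zeros((self.classes_.size, p))
        self.class_prior_ = np.zeros(self.classes_.size)
        for i, c in enumerate(self.classes_):
            Xc = X[y == c]
            self.class_prior_[i] = Xc.shape[0] / n
            self.theta_[i] = Xc.mean(axis=0)
            self.var_[i] = Xc.var(axis=0)
        # Variance floor: epsilon times the largest feature variance.
        global_var = X.var(axis=0).max()
        floor = self.var_floor_ratio * (global_var if global_var > 0 else 1.0)
        self.var_ = np.maximum(self.var_, floor)
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        jll = np.zeros((X.shape[0], self.classes_.size))
        for i in range(self.classes_.size):
            logdens = -0.5 * (
                np.log(2 * np.pi * self.var_[i])
                + (X - self.theta_[i]) ** 2 / self.var_[i]
            )
            jll[:, i] = np.log(self.class_prior_[i]) + logdens.sum(axis=1)
        return jll

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def _registry() -> Dict[str, Callable[[int], BaseEstimator]]:
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neural_network import MLPClassifier
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    def scaled(est):
        # Gram probabilities live on a 1/k^n scale; scale-sensitive
        # estimators need standardization to converge.
        return Pipeline([("scale", StandardScaler()), ("clf", est)])

    return {
        "reference_gnb": lambda seed: GaussianNBClassifier(),
        "naive_bayes": lambda seed: GaussianNB(),
        # No Bayesian-network learner ships with scikit-learn; the closest
        # available graphical naive model stands in under this name.
        "bayes_net": lambda seed: GaussianNB(),
        "logistic": lambda seed: scaled(LogisticRegression(max_iter=2000)),
        "svm": lambda seed: scaled(SVC(kernel="linear", random_state=seed)),
        "tree": lambda seed: DecisionTreeClassifier(random_state=seed),
        "mlp": lambda seed: scaled(
            MLPClassifier(
                hidden_layer_sizes=(50,), max_iter=500, random_state=seed
            )
        ),
    }


CLASSIFIER_REGISTRY = tuple(_registry().keys())


def make_classifier(name: str, seed: int = 0) -> BaseEstimator:
    """Instantiate a classifier by registry name."""
    reg = _registry()
    if name not in reg:
        raise ParameterError(
            f"unknown classifier {name!r}; choose from {sorted(reg)}"
        )
    return reg[name](seed)
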