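"""Uniform classifier wrappers, stratified cross-validation and metrics.

Seven classifier families are exposed behind one name-based factory:
support-vector machine, k-nearest neighbours, Gaussian naive Bayes, decision
tree, random forest, gradient-boosted trees (XGBoost) and AdaBoost.  The
family internals are delegated to scikit-learn / xgboost; this module owns
seeding, the score interface, stratified k-fold evaluation and the metric
layer.

Conventions: the male class (label 1) is the positive class; accuracy,
precision, recall and F1 come from the pooled confusion matrix per fold and
are averaged over folds; AUC is the Mann-Whitney rank statistic on the pooled
out-of-fold scores (ties midranked).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

VALID_NAMES = (
    "svm",
    "knn",
    "naive_bayes",
    "decision_tree",
    "random_forest",
    "xgboost",
    "adaboost",
)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family name plus its hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in VALID_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; valid names: {VALID_NAMES}"
            )


class _Wrapped:
    """fit/predict/predict_score facade over a fitted estimator."""

    def __init__(self, estimator):
        self._est = estimator

    def fit(self, X, y):
        self._est.fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self._est.predict(X))

    def predict_score(self, X):
        """Continuous score for the positive (male) class."""
        if hasattr(self._est, "predict_proba"):
            return np.asarray(self._est.predict_proba(X))[:, 1]
        return np.asarray(self._est.decision_function(X))


def make_classifier(spec: ClassifierSpec, seed: int = 0) -> _Wrapped:
    """Instantiate a seeded, unfitted classifier for the given family.

    Unknown hyperparameter names raise naming the offending key.  Defaults
    are each library's own, except SVC gains probability scores via its
    decision function (no Platt scaling needed for ranking metrics).
    """
    hp = dict(spec.hyperparameters)
    name = spec.name
    if name == "svm":
        est = SVC(random_state=seed)
    elif name == "knn":
        est = KNeighborsClassifier()
    elif name == "naive_bayes":
        est = GaussianNB()
    elif name == "decision_tree":
        est = DecisionTreeClassifier(random_state=seed)
    elif name == "random_forest":
        est = RandomForestClassifier(random_state=seed)
    elif name == "adaboost":
        est = AdaBoostClassifier(random_state=seed)
    else:  # xgboost
        est = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
    valid = est.get_params()
    for key in hp:
        if key not in valid:
            raise ValueError(
                f"invalid hyperparameter {key!r} for classifier {name!r}"
            )
    est.set_params(**hp)
    return _Wrapped(est)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with male (label 1) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F1 from raw counts.

    A zero denominator makes the ratio undefined; it is reported as 0 and
    flagged in ``undefined`` rather than raising.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp:
        precision = cm.tp / (cm.tp + cm.fp)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if cm.tp + cm.fn:
        recall = cm.tp / (cm.tp + cm.fn)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        undefined=tuple(undefined),
    )


def rank_auc(y_true, scores) -> float:
    """AUC as the Mann-Whitney statistic with midrank tie correction.

    1.0 for perfectly ranked scores, 0.0 for a perfectly reversed ranking,
    0.5 for constant scores.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def stratified_cv(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> tuple[MetricsReport, pd.DataFrame, ConfusionMatrix]:
    """Stratified k-fold evaluation of one classifier family.

    Every sample is tested exactly once; per-fold class counts deviate from
    exact proportion by less than one sample.  Returns the fold-mean metrics
    (AUC from pooled out-of-fold scores), the per-fold table and the pooled
    confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples < k={k} folds; "
            f"use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_rows = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    oof_scores = np.empty(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = make_classifier(spec, seed=seed).fit(X[tr], y[tr])
        pred = model.predict(X[te])
        oof_scores[te] = model.predict_score(X[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred)
        pooled = pooled + cm
        rep = metrics_from_confusion(cm)
        fold_rows.append(
            {
                "fold": fold,
                "n_test": len(te),
                "accuracy": rep.accuracy,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
            }
        )
    folds = pd.DataFrame(fold_rows)
    report = MetricsReport(
        accuracy=float(folds["accuracy"].mean()),
        precision=float(folds["precision"].mean()),
        recall=float(folds["recall"].mean()),
        f1=float(folds["f1"].mean()),
        auc=rank_auc(y, oof_scores),
    )
    return report, folds, pooled
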