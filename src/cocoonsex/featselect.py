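"""Mutual-information feature ranking and recursive feature elimination.

Feature importance is the information gain IG(X_i; Y) = H(X_i) - H(X_i | Y)
in bits, a model-free dependence measure: with a binary label it lies in
[0, 1].  Continuous features are discretized into equal-frequency bins before
the entropies are computed.  RFE repeatedly evaluates the surviving feature
set by stratified cross-validation, re-ranks it by information gain, and
drops the single least informative feature, down to one feature; the best
subset is the one with the highest recorded CV accuracy (ties go to the
smaller subset).

Note the ranking is model-agnostic — the same MI ordering drives elimination
for every classifier family — unlike classic RFE which reuses model weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .classify import ClassifierSpec, stratified_cv


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; low-cardinality inputs pass through as codes."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(x, edges)


def mutual_info_gain(x: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Information gain IG(X; Y) = H(X) - H(X|Y) in bits.

    x is discretized into equal-frequency bins (already-discrete inputs keep
    their levels); entropies use base-2 logs with the 0*log0 = 0 convention.
    A constant x gives 0.  Negative floating-point residue is clipped at 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) < 10:
        raise ValueError(f"need n >= 10 samples, got {len(x)}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    codes = _discretize(x, bins)
    n = len(codes)
    n_levels = codes.max() + 1
    h_x = _scipy_entropy(np.bincount(codes, minlength=n_levels), base=2)
    h_x_given_y = 0.0
    for c in classes:
        mask = y == c
        counts = np.bincount(codes[mask], minlength=n_levels)
        h_x_given_y += mask.mean() * _scipy_entropy(counts, base=2)
    return max(0.0, float(h_x - h_x_given_y))


@dataclass(frozen=True)
class MIRanking:
    """Per-feature information gain (bits) and the descending-IG order."""

    gains: np.ndarray
    order: np.ndarray  # feature indices, best first
    bins: int


def rank_features(X: np.ndarray, y: np.ndarray, bins: int = 10) -> MIRanking:
    """Rank columns of X by information gain with the label.

    Ties are broken by ascending feature index, so the ranking is
    deterministic and permutation-equivariant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    gains = np.array([mutual_info_gain(X[:, j], y, bins) for j in range(X.shape[1])])
    # stable sort on -gain keeps ascending index order within ties
    order = np.argsort(-gains, kind="stable")
    return MIRanking(gains=gains, order=order, bins=bins)


@dataclass(frozen=True)
class RFEStep:
    features: tuple[int, ...]
    removed: int | None  # feature dropped AFTER evaluating this set
    metrics: dict


@dataclass(frozen=True)
class RFEPath:
    """The full elimination trajectory and the selected best subset."""

    steps: tuple[RFEStep, ...]
    best_index: int

    @property
    def best_features(self) -> tuple[int, ...]:
        return self.steps[self.best_index].features

    @property
    def best_metrics(self) -> dict:
        return self.steps[self.best_index].metrics

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps):
            rows.append(
                {
                    "iteration": i,
                    "n_features": len(s.features),
                    "removed_feature": -1 if s.removed is None else s.removed,
                    **{k: s.metrics[k] for k in
                       ("accuracy", "precision", "recall", "f1", "auc")},
                }
            )
        return pd.DataFrame(rows)


def rfe(
    X: np.ndarray,
    y: np.ndarray,
    model_name: str = "xgboost",
    k: int = 10,
    seed: int = 0,
    bins: int = 10,
    min_features: int = 1,
    hyperparameters: dict | None = None,
) -> RFEPath:
    """Recursive feature elimination guided by mutual-information ranking.

    Each iteration scores the current feature set by stratified k-fold CV,
    then removes the lowest-IG feature (IG recomputed on the survivors).
    Runs down to ``min_features`` and selects the subset with the highest CV
    accuracy; among ties the smallest subset wins.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    active = list(range(X.shape[1]))
    spec = ClassifierSpec(model_name, hyperparameters or {})
    steps: list[RFEStep] = []
    while True:
        Xa = X[:, active]
        report, _, _ = stratified_cv(spec, Xa, y, k=k, seed=seed)
        metrics = report.as_dict()
        if len(active) <= min_features:
            steps.append(RFEStep(tuple(active), None, metrics))
            break
        ranking = rank_features(Xa, y, bins)
        drop_local = int(ranking.order[-1])
        removed = active[drop_local]
        steps.append(RFEStep(tuple(active), removed, metrics))
        active.pop(drop_local)
    accs = np.array([s.metrics["accuracy"] for s in steps])
    sizes = np.array([len(s.features) for s in steps])
    best = np.lexsort((sizes, -accs))[0]
    return RFEPath(steps=tuple(steps), best_index=int(best))
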