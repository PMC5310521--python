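"""Classifier training and evaluation protocol.

Three model families - CART decision tree (DT), random forest (RF, 100
trees) and partial least squares regression used as a classifier (PLS,
predicted value cut at 0.5) - are evaluated by stratified 10-fold
cross-validation.  Inside every fold, descriptors are re-selected on the
training compounds only, by absolute point-biserial (Pearson) correlation
with the 0/1 label:

* DT/RF use a budget of one tenth of the training-set size;
* PLS tries 5, 10, 20 and 50 descriptors and reports the best grid value,
  with the number of latent components capped at one tenth of the number of
  data points.

Performance is the balanced accuracy (mean of sensitivity and specificity)
over the pooled out-of-fold predictions.  RF models are additionally rebuilt
under 100 different forest seeds to give a performance distribution rather
than a single number.

All randomness (fold assignment, forest seeds) derives from one master seed
through counter-based substreams, so every run is exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .labelling import ModellingDataset

__all__ = [
    "ModelConfig",
    "ModelRun",
    "StratificationError",
    "UndefinedMetric",
    "stratified_folds",
    "select_descriptors",
    "descriptor_budget",
    "balanced_accuracy",
    "cross_validate",
    "rf_distribution",
    "descriptor_importance",
]

METHODS = ("decision_tree", "random_forest", "pls")

_METHOD_ALIASES = {
    "dt": "decision_tree",
    "decision_tree": "decision_tree",
    "rf": "random_forest",
    "random_forest": "random_forest",
    "pls": "pls",
}


class StratificationError(ValueError):
    """A class has fewer members than the number of folds."""


class UndefinedMetric(ValueError):
    """Balanced accuracy is undefined (a class is absent from y_true)."""


@dataclass
class ModelConfig:
    method: str = "decision_tree"
    k_folds: int = 10
    pls_descriptor_grid: tuple[int, ...] = (5, 10, 20, 50)
    rf_n_seeds: int = 100
    rf_n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            self.method = _METHOD_ALIASES[self.method.lower()]
        except KeyError:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}") from None
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not self.pls_descriptor_grid:
            raise ValueError("pls_descriptor_grid must be non-empty")


@dataclass
class ModelRun:
    """One cross-validated model evaluation."""

    method: str
    seed: int
    balanced_accuracy: float
    #: mean of per-fold balanced accuracies (where defined); the headline
    #: number is the pooled out-of-fold value above
    fold_mean_balanced_accuracy: float
    oof_predictions: np.ndarray
    fold_assignment: np.ndarray
    selected_descriptors: list[np.ndarray]
    pls_n_descriptors: int | None = None
    pls_grid_accuracies: dict[int, float] | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "balanced_accuracy": self.balanced_accuracy,
            "fold_mean_balanced_accuracy": self.fold_mean_balanced_accuracy,
            "pls_n_descriptors": self.pls_n_descriptors,
            "pls_grid_accuracies": self.pls_grid_accuracies,
            "selected_descriptors": [list(map(int, s)) for s in self.selected_descriptors],
        }


def _substream_seed(*path: int) -> int:
    """Deterministic 31-bit seed for a named substream of the master seed."""
    return int(np.random.default_rng(list(path)).integers(2**31))


def stratified_folds(labels: Sequence[int], k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition indices into k folds preserving the class ratio.

    Each fold's class counts are within +-1 of the proportional share, and
    per-class remainders go to the currently smallest folds so total fold
    sizes also differ by at most one.
    """
    labels = np.asarray(labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() < k:
        raise StratificationError(
            f"smallest class has {class_counts.min()} members, fewer than k={k}"
        )
    folds: list[list[int]] = [[] for _ in range(k)]
    sizes = np.zeros(k, dtype=int)
    # larger classes first so their remainders set the size pattern
    for cls in classes[np.argsort(-class_counts, kind="stable")]:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        base, extra = divmod(len(idx), k)
        order = np.lexsort((np.arange(k), sizes))  # smallest folds first, tie by index
        cursor = 0
        for pos, f in enumerate(order):
            take = base + (1 if pos < extra else 0)
            folds[f].extend(idx[cursor : cursor + take].tolist())
            sizes[f] += take
            cursor += take
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _correlations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column with y, plus a usability mask (non-constant)."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    usable = sx > 1e-12
    r = np.zeros(X.shape[1])
    if sy > 0:
        r[usable] = (Xc[:, usable].T @ yc) / (sx[usable] * sy)
    return r, usable


def select_descriptors(train_features: np.ndarray, train_labels: np.ndarray, n: int) -> np.ndarray:
    """Indices of the top-n descriptors by |Pearson r| with the 0/1 label.

    Constant (zero-variance) descriptors are never selected; ties break by
    ascending descriptor index.  If fewer than n descriptors are usable, all
    usable ones are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r, usable = _correlations(np.asarray(train_features, dtype=float), np.asarray(train_labels, dtype=float))
    candidates = np.flatnonzero(usable)
    if len(candidates) < n:
        warnings.warn(
            f"only {len(candidates)} usable descriptors (< {n} requested); selecting all",
            stacklevel=2,
        )
        n = len(candidates)
    # sort by (-|r|, index); lexsort keys are read last-first
    order = np.lexsort((candidates, -np.abs(r[candidates])))
    return candidates[order[:n]]


def descriptor_budget(method: str, n_train: int, pls_grid: tuple[int, ...] = (5, 10, 20, 50)):
    """Descriptor count for DT/RF (one tenth of the training set) or the PLS grid."""
    method = _METHOD_ALIASES[method.lower()]
    if n_train < 10:
        raise ValueError("need at least 10 training compounds")
    if method == "pls":
        return tuple(pls_grid)
    return n_train // 10


def pls_component_cap(n_points: int) -> int:
    """Maximum latent components: one tenth of the number of data points."""
    return max(1, n_points // 10)


def balanced_accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """(sensitivity + specificity) / 2 for 0/1 labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    pos = y_true == 1
    neg = y_true == 0
    if not pos.any() or not neg.any():
        raise UndefinedMetric("a class is absent from y_true; balanced accuracy undefined")
    sensitivity = (y_pred[pos] == 1).mean()
    specificity = (y_pred[neg] == 0).mean()
    return float((sensitivity + specificity) / 2.0)


def _fit_predict(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    model_seed: int,
    n_components: int | None = None,
    n_trees: int = 100,
) -> np.ndarray:
    if method == "decision_tree":
        model = DecisionTreeClassifier(random_state=model_seed)
        model.fit(X_train, y_train)
        return model.predict(X_test).astype(np.int64)
    if method == "random_forest":
        model = RandomForestClassifier(n_estimators=n_trees, random_state=model_seed)
        model.fit(X_train, y_train)
        return model.predict(X_test).astype(np.int64)
    if method == "pls":
        model = PLSRegression(n_components=n_components, scale=False)
        model.fit(X_train, y_train.astype(float))
        raw = model.predict(X_test).ravel()
        return (raw >= 0.5).astype(np.int64)  # exactly 0.5 -> class 1
    raise ValueError(f"unknown method {method!r}")


def _cv_pass(
    dataset: ModellingDataset,
    config: ModelConfig,
    folds: list[np.ndarray],
    n_descriptors: int | None,
    labels: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray, list[np.ndarray]]:
    """One full CV pass; returns (pooled BA, fold-mean BA, oof preds, selections)."""
    X = dataset.features
    y = dataset.labels if labels is None else labels
    n = len(y)
    oof = np.full(n, -1, dtype=np.int64)
    fold_bas = []
    selections: list[np.ndarray] = []
    for fold_i, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        if n_descriptors is None:
            budget = descriptor_budget(config.method, len(train_idx))
        else:
            budget = n_descriptors
        sel = select_descriptors(X[train_idx], y[train_idx], budget)
        selections.append(sel)
        n_comp = None
        if config.method == "pls":
            n_comp = min(pls_component_cap(n), len(sel), len(train_idx) - 1)
        preds = _fit_predict(
            config.method,
            X[np.ix_(train_idx, sel)],
            y[train_idx],
            X[np.ix_(test_idx, sel)],
            model_seed=_substream_seed(config.seed, 202, fold_i),
            n_components=n_comp,
            n_trees=config.rf_n_trees,
        )
        oof[test_idx] = preds
        try:
            fold_bas.append(balanced_accuracy(y[test_idx], preds))
        except UndefinedMetric:
            pass
    pooled = balanced_accuracy(y, oof)
    fold_mean = float(np.mean(fold_bas)) if fold_bas else pooled
    return pooled, fold_mean, oof, selections


def cross_validate(
    dataset: ModellingDataset,
    config: ModelConfig,
    labels: np.ndarray | None = None,
) -> ModelRun:
    """Stratified k-fold cross-validation under the configured protocol.

    ``labels`` overrides the dataset's labels (used by y-randomisation, which
    must re-select descriptors against the shuffled labels); folds are
    re-stratified on the labels actually modelled.
    """
    y = dataset.labels if labels is None else np.asarray(labels)
    rng = np.random.default_rng([config.seed, 101])
    folds = stratified_folds(y, config.k_folds, rng)
    if config.method != "pls":
        pooled, fold_mean, oof, selections = _cv_pass(dataset, config, folds, None, labels=y)
        return ModelRun(
            method=config.method,
            seed=config.seed,
            balanced_accuracy=pooled,
            fold_mean_balanced_accuracy=fold_mean,
            oof_predictions=oof,
            fold_assignment=_fold_assignment(folds, len(y)),
            selected_descriptors=selections,
        )
    grid_results: dict[int, tuple] = {}
    for n_desc in config.pls_descriptor_grid:
        grid_results[n_desc] = _cv_pass(dataset, config, folds, n_desc, labels=y)
    # best balanced accuracy; ties -> smallest grid value (parsimony)
    best_n = min(grid_results, key=lambda n: (-grid_results[n][0], n))
    pooled, fold_mean, oof, selections = grid_results[best_n]
    return ModelRun(
        method="pls",
        seed=config.seed,
        balanced_accuracy=pooled,
        fold_mean_balanced_accuracy=fold_mean,
        oof_predictions=oof,
        fold_assignment=_fold_assignment(folds, len(y)),
        selected_descriptors=selections,
        pls_n_descriptors=best_n,
        pls_grid_accuracies={n: res[0] for n, res in grid_results.items()},
    )


def _fold_assignment(folds: list[np.ndarray], n: int) -> np.ndarray:
    assignment = np.full(n, -1, dtype=np.int64)
    for f, idx in enumerate(folds):
        assignment[idx] = f
    return assignment


def rf_distribution(
    dataset: ModellingDataset,
    config: ModelConfig,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-validated balanced accuracy under ``rf_n_seeds`` forest seeds.

    Folds and per-fold descriptor selections are fixed by the master seed
    (they do not depend on the forest seed), so they are computed once and
    each forest seed refits the trees only.
    """
    if config.method != "random_forest":
        raise ValueError("rf_distribution requires method='random_forest'")
    y = dataset.labels if labels is None else np.asarray(labels)
    X = dataset.features
    n = len(y)
    rng = np.random.default_rng([config.seed, 101])
    folds = stratified_folds(y, config.k_folds, rng)
    prepared = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        sel = select_descriptors(X[train_idx], y[train_idx], descriptor_budget("rf", len(train_idx)))
        prepared.append((train_idx, test_idx, sel))
    accuracies = np.empty(config.rf_n_seeds)
    for m in range(config.rf_n_seeds):
        oof = np.full(n, -1, dtype=np.int64)
        for fold_i, (train_idx, test_idx, sel) in enumerate(prepared):
            oof[test_idx] = _fit_predict(
                "random_forest",
                X[np.ix_(train_idx, sel)],
                y[train_idx],
                X[np.ix_(test_idx, sel)],
                model_seed=_substream_seed(config.seed, 303, m, fold_i),
                n_trees=config.rf_n_trees,
            )
        accuracies[m] = balanced_accuracy(y, oof)
    return accuracies


def descriptor_importance(
    dataset: ModellingDataset,
    n_models: int = 100,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Per-class descriptor importance from whole-dataset random forests.

    Fits ``n_models`` forests on the full dataset (no cross-validation) with
    the usual one-tenth descriptor budget and measures, for every selected
    descriptor, the drop in per-class accuracy when that descriptor's column
    is permuted - one importance per class direction, mirroring the two rank
    columns of a saline-vs-CMC style analysis.  Returns a table indexed by
    descriptor name with mean importances and 1-based ranks per direction.
    """
    config = config or ModelConfig(method="random_forest")
    X = dataset.features
    y = dataset.labels
    sel = select_descriptors(X, y, max(1, len(y) // 10))
    Xs = X[:, sel]
    drops = np.zeros((2, len(sel)))
    for m in range(n_models):
        seed_m = _substream_seed(config.seed, 404, m)
        forest = RandomForestClassifier(
            n_estimators=config.rf_n_trees, random_state=seed_m
        ).fit(Xs, y)
        base_pred = forest.predict(Xs)
        perm_rng = np.random.default_rng([config.seed, 405, m])
        base_acc = [(base_pred[y == c] == c).mean() for c in (0, 1)]
        for j in range(len(sel)):
            Xp = Xs.copy()
            Xp[:, j] = perm_rng.permutation(Xp[:, j])
            pred = forest.predict(Xp)
            for c in (0, 1):
                drops[c, j] += base_acc[c] - (pred[y == c] == c).mean()
    drops /= n_models
    names = [dataset.feature_names[i] for i in sel]
    frame = pd.DataFrame(
        {
            "importance_class_a": drops[0],
            "importance_class_b": drops[1],
        },
        index=pd.Index(names, name="descriptor"),
    )
    frame["rank_class_a"] = frame["importance_class_a"].rank(ascending=False, method="min").astype(int)
    frame["rank_class_b"] = frame["importance_class_b"].rank(ascending=False, method="min").astype(int)
    return frame.sort_values("rank_class_a")
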