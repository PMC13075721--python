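"""Wrapper fitness for feature subsets.

The selector scores a candidate subset sK of the N-column feature table by

    fitness(sK) = w1 * Acc(sK) - w2 * |sK| / N

where Acc(sK) is the stratified k-fold cross-validated accuracy of a
regularized linear discriminant classifier restricted to sK's columns, and
the second term penalizes subset size. The per-feature heuristic used by the
ant-colony stage is a plug-in mutual-information estimate between each
column (equal-frequency binned) and the class labels, in bits.

Everything here is closed-form and deterministic given (table, subset,
config): the discriminant has no iterative fitting and the fold assignment
is a seeded permutation, so identical calls always return identical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eeg_features import FeatureTable

__all__ = [
    "FitnessConfig",
    "Subset",
    "mutual_information",
    "subset_accuracy",
    "fitness",
    "FitnessEvaluator",
]


@dataclass(frozen=True)
class FitnessConfig:
    w1: float = 0.9
    w2: float = 0.1
    cv_folds: int = 3
    classifier_seed: int = 0
    n_bins: int = 10          # equal-frequency bins for mutual information
    shrinkage: float = 0.1    # covariance shrinkage toward scaled identity

    def __post_init__(self):
        if not self.w1 > 0:
            raise ValueError("w1 must be positive")
        if self.w2 < 0:
            raise ValueError("w2 must be non-negative")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must be in [0, 1]")


@dataclass
class Subset:
    """A binary feature-inclusion vector with an optional cached fitness."""

    include: np.ndarray
    cached_fitness: float | None = None

    def __post_init__(self):
        self.include = np.asarray(self.include).astype(bool)

    @property
    def size(self) -> int:
        return int(np.count_nonzero(self.include))

    def __len__(self) -> int:
        return self.include.size


def _as_mask(subset, n_features: int) -> np.ndarray:
    mask = subset.include if isinstance(subset, Subset) else np.asarray(subset).astype(bool)
    if mask.shape != (n_features,):
        raise ValueError("subset length does not match the table")
    return mask


# ---------------------------------------------------------------------------
# Mutual information heuristic
# ---------------------------------------------------------------------------

def _equal_frequency_bins(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning; ties share a bin, so any strictly
    monotone transform of the column yields identical bins."""
    n = column.size
    order = np.sort(column)
    first_rank = np.searchsorted(order, column, side="left")
    return (first_rank * n_bins) // n


def mutual_information(column, labels, n_bins: int = 10) -> float:
    """Plug-in MI estimate (bits) between a binned column and class labels."""
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(column)):
        raise ValueError("feature column must be finite")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("labels must contain at least 2 classes")
    bins = _equal_frequency_bins(column, n_bins)
    n = column.size
    mi = 0.0
    for b in np.unique(bins):
        pb = np.count_nonzero(bins == b) / n
        for c in classes:
            joint = np.count_nonzero((bins == b) & (labels == c)) / n
            if joint > 0:
                pc = np.count_nonzero(labels == c) / n
                mi += joint * math.log2(joint / (pb * pc))
    return max(mi, 0.0)


def mi_heuristic(table: FeatureTable, n_bins: int = 10) -> np.ndarray:
    """Per-feature MI with the labels; the ant heuristic vector."""
    return np.array([mutual_information(table.values[:, j], table.labels, n_bins)
                     for j in range(table.n_features)])


# ---------------------------------------------------------------------------
# Regularized linear discriminant, stratified CV
# ---------------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per sample)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has only {idx.size} samples; lower cv_folds below {k}")
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % k
    return assignment


class _ShrunkLDA:
    """Closed-form linear discriminant with covariance shrinkage
    (1-lam)*S + lam*(tr(S)/p)*I; ties in the class scores go to the
    lower-coded class."""

    def __init__(self, shrinkage: float = 0.1):
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ShrunkLDA":
        self.classes_ = np.unique(y)
        n, p = X.shape
        means, priors = [], []
        scatter = np.zeros((p, p))
        for c in self.classes_:
            Xc = X[y == c]
            mu = Xc.mean(axis=0)
            means.append(mu)
            priors.append(Xc.shape[0] / n)
            d = Xc - mu
            scatter += d.T @ d
        cov = scatter / max(n - self.classes_.size, 1)
        lam = self.shrinkage
        target = (np.trace(cov) / p) * np.eye(p) if p > 0 else cov
        cov = (1 - lam) * cov + lam * target
        cov += 1e-10 * np.eye(p)  # numerical floor for constant columns
        self.means_ = np.asarray(means)
        self.log_priors_ = np.log(np.asarray(priors))
        self.coef_ = np.linalg.solve(cov, self.means_.T).T          # C x p
        self.intercept_ = (-0.5 * np.einsum("ij,ij->i", self.means_, self.coef_)
                           + self.log_priors_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self.coef_.T + self.intercept_
        return self.classes_[np.argmax(scores, axis=1)]


def subset_accuracy(table: FeatureTable, subset, cfg: FitnessConfig = FitnessConfig()) -> float:
    """Stratified k-fold CV accuracy of the shrunk LDA on the subset's columns."""
    mask = _as_mask(subset, table.n_features)
    if not mask.any():
        raise ValueError("subset must include at least one feature")
    X = table.values[:, mask]
    y = np.asarray(table.labels)
    folds = stratified_folds(y, cfg.cv_folds, cfg.classifier_seed)
    correct = 0
    for f in range(cfg.cv_folds):
        test = folds == f
        clf = _ShrunkLDA(cfg.shrinkage).fit(X[~test], y[~test])
        correct += int(np.count_nonzero(clf.predict(X[test]) == y[test]))
    return correct / y.size


def fitness(table: FeatureTable, subset, cfg: FitnessConfig = FitnessConfig()) -> float:
    """w1 * Acc(sK) - w2 * |sK| / N; an empty subset scores -inf so it can
    never win an argmax."""
    mask = _as_mask(subset, table.n_features)
    if not mask.any():
        return -math.inf
    acc = subset_accuracy(table, mask, cfg)
    return cfg.w1 * acc - cfg.w2 * (int(mask.sum()) / table.n_features)


class FitnessEvaluator:
    """Memoizing fitness for the optimizer: fold assignment is computed once
    and each distinct subset is scored exactly once per evaluator."""

    def __init__(self, table: FeatureTable, cfg: FitnessConfig = FitnessConfig()):
        if np.unique(table.labels).size < 2:
            raise ValueError("feature table has a single class; nothing to separate")
        self.table = table
        self.cfg = cfg
        self.n_features = table.n_features
        self._X = table.values
        self._y = np.asarray(table.labels)
        self._folds = stratified_folds(self._y, cfg.cv_folds, cfg.classifier_seed)
        self._cache: dict = {}
        self.n_evaluations = 0

    def __call__(self, mask) -> float:
        mask = np.asarray(mask).astype(bool)
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        if not mask.any():
            value = -math.inf
        else:
            X = self._X[:, mask]
            correct = 0
            for f in range(self.cfg.cv_folds):
                test = self._folds == f
                clf = _ShrunkLDA(self.cfg.shrinkage).fit(X[~test], self._y[~test])
                correct += int(np.count_nonzero(clf.predict(X[test]) == self._y[test]))
            acc = correct / self._y.size
            value = self.cfg.w1 * acc - self.cfg.w2 * (int(mask.sum()) / self.n_features)
            self.n_evaluations += 1
        self._cache[key] = value
        return value
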