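"""Probabilistic neural network (Parzen-window Bayes classifier) with
smoothing-factor tuning, stratified holdout, and N-fold cross-validation.

A PNN has four layers and no iterative weight training: the input layer
receives the feature vector; the pattern layer holds one Gaussian kernel
exp(-||x - w_k||^2 / (2 sigma^2)) per stored training exemplar w_k; the
summation layer averages the kernels per class (normalized by class size,
i.e. uniform class priors, because the groups are unbalanced); the decision
layer takes the argmax.  Exact ties resolve deterministically to the first
(lowest) class label.

Scores are computed in the log domain (log-sum-exp), so the sigma -> 0 limit
degrades gracefully to nearest-exemplar classification and large feature
distances never underflow to an uninformative 0/0.

Cross-validation and sigma tuning use in-package stratified shuffled folds
driven by one explicit seed; feature columns are z-scored with training-fold
statistics only, so no information leaks from held-out subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

from .optimize import FeatureMatrix

__all__ = [
    "PNNClassifier",
    "CVReport",
    "default_sigma_grid",
    "stratified_folds",
    "tune_sigma",
    "holdout_split",
    "cross_validate",
]


def default_sigma_grid() -> np.ndarray:
    """Smoothing factors 0.1 .. 2.0 in steps of 0.1 (20 values)."""
    return np.round(np.arange(1, 21) * 0.1, 10)


@dataclass
class CVReport:
    """Per-fold accuracies (%) of an N-fold cross-validation run."""

    fold_accuracies: list[float]
    mean: float
    std: float
    n_folds: int
    seed: int
    sigma: float

    def to_dict_report(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "mean": self.mean,
            "std": self.std,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "sigma": self.sigma,
        }


class PNNClassifier(ClassifierMixin, BaseEstimator):
    """Parzen-window probabilistic neural network.

    Parameters
    ----------
    sigma : float
        Smoothing factor of the Gaussian kernels (in feature units).
    priors : "uniform" or "proportional"
        "uniform" normalizes each class's kernel sum by its exemplar count;
        "proportional" weights classes by their training frequency.
    """

    def __init__(self, sigma: float = 1.5, priors: str = "uniform") -> None:
        self.sigma = sigma
        self.priors = priors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PNNClassifier":
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.priors not in ("uniform", "proportional"):
            raise ValueError(f"priors must be 'uniform' or 'proportional', got {self.priors!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("PNN needs at least one exemplar of each of >= 2 classes")
        self.X_ = X.copy()
        self.y_ = y.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def _log_scores(self, X: np.ndarray) -> np.ndarray:
        """Log of the class-normalized kernel sums, shape (n_samples, n_classes)."""
        if not hasattr(self, "X_"):
            raise RuntimeError("PNNClassifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted dimension {self.n_features_in_}"
            )
        d2 = cdist(X, self.X_, metric="sqeuclidean")
        log_k = -d2 / (2.0 * self.sigma**2)
        n_total = self.X_.shape[0]
        out = np.empty((X.shape[0], self.classes_.size))
        with np.errstate(divide="ignore"):
            for ci, c in enumerate(self.classes_):
                mask = self.y_ == c
                n_c = int(mask.sum())
                ls = logsumexp(log_k[:, mask], axis=1)
                if self.priors == "uniform":
                    out[:, ci] = ls - np.log(n_c)
                else:  # proportional: prior n_c/n cancels the 1/n_c normalizer
                    out[:, ci] = ls - np.log(n_total)
        return out

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class log scores for audit (higher = more likely)."""
        return self._log_scores(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        ls = self._log_scores(X)
        # softmax; an all -inf row (possible only at extreme sigma) -> uniform
        shift = np.max(ls, axis=1, keepdims=True)
        finite = np.isfinite(shift[:, 0])
        p = np.full(ls.shape, 1.0 / ls.shape[1])
        if finite.any():
            z = np.exp(ls[finite] - shift[finite])
            p[finite] = z / z.sum(axis=1, keepdims=True)
        return p

    def predict(self, X: np.ndarray) -> np.ndarray:
        ls = self._log_scores(X)
        # np.argmax takes the first maximum: exact ties resolve to the
        # lowest class label (classes_ is sorted)
        return self.classes_[np.argmax(ls, axis=1)]


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Deterministic stratified shuffled folds.

    Each class's indices are shuffled and dealt across folds; each class's
    surplus goes to the currently least-loaded folds, so overall fold sizes
    differ by at most one.  Returns the list of test-index arrays.
    """
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < n_folds = {n_folds}; "
            "use fewer folds"
        )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    load = np.zeros(n_folds, dtype=int)
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        base, extra = divmod(idx.size, n_folds)
        order = np.argsort(load, kind="stable")  # least-loaded folds get the surplus
        sizes = np.full(n_folds, base)
        sizes[order[:extra]] += 1
        pos = 0
        for f in range(n_folds):
            folds[f].extend(idx[pos : pos + sizes[f]].tolist())
            load[f] += sizes[f]
            pos += sizes[f]
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """z-score columns by training statistics only; constant columns pass through."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _as_xy(features: FeatureMatrix | np.ndarray, y: np.ndarray | None):
    if isinstance(features, FeatureMatrix):
        return features.X, features.y
    if y is None:
        raise ValueError("labels required when features is a plain array")
    return np.asarray(features, dtype=float), np.asarray(y)


def tune_sigma(
    features: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    sigmas: Sequence[float] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    priors: str = "uniform",
    standardize: bool = True,
) -> float:
    """Grid-search the smoothing factor by stratified cross-validated accuracy.

    Ties break to the smaller sigma.  The default grid is 0.1 .. 2.0 in
    steps of 0.1.
    """
    X, yy = _as_xy(features, y)
    grid = np.asarray(default_sigma_grid() if sigmas is None else sigmas, dtype=float)
    if grid.size == 0 or not (grid > 0).all():
        raise ValueError("sigma grid must be non-empty and positive")
    if grid.size == 1:
        return float(grid[0])
    n_folds = min(n_folds, int(np.unique(yy, return_counts=True)[1].min()))
    folds = stratified_folds(yy, n_folds, seed)
    best_sigma, best_correct = None, -1
    for sigma in np.sort(grid):
        correct = 0
        for test_idx in folds:
            train_mask = np.ones(yy.size, dtype=bool)
            train_mask[test_idx] = False
            Xtr, Xte = X[train_mask], X[test_idx]
            if standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            model = PNNClassifier(sigma=float(sigma), priors=priors).fit(Xtr, yy[train_mask])
            correct += int((model.predict(Xte) == yy[test_idx]).sum())
        if correct > best_correct:  # strict: tie keeps the smaller sigma
            best_sigma, best_correct = float(sigma), correct
    assert best_sigma is not None
    return best_sigma


def holdout_split(
    features: FeatureMatrix,
    n_test_per_class: dict[int, int],
    seed: int,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Random stratified train/test split with the given test counts per class.

    Reproducible for a fixed seed; original subject order is preserved
    within each part.
    """
    y = features.y
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(y.size, dtype=bool)
    for c, n_test in n_test_per_class.items():
        idx = np.flatnonzero(y == c)
        if n_test < 0 or n_test > idx.size:
            raise ValueError(
                f"cannot hold out {n_test} of {idx.size} subjects in class {c}"
            )
        chosen = rng.choice(idx, size=n_test, replace=False)
        test_mask[chosen] = True

    def _subset(mask: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            values=features.values.iloc[mask], labels=y[mask], dropped=[]
        )

    return _subset(~test_mask), _subset(test_mask)


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    n_folds: int = 10,
    sigma: float = 1.5,
    seed: int = 0,
    priors: str = "uniform",
    standardize: bool = True,
) -> CVReport:
    """Stratified N-fold cross-validation of the PNN at a fixed sigma.

    Per-fold accuracy is reported in percent with mean and (population) std;
    folds are shuffled deterministically by the seed.
    """
    X, yy = _as_xy(features, y)
    folds = stratified_folds(yy, n_folds, seed)
    accs = []
    for test_idx in folds:
        train_mask = np.ones(yy.size, dtype=bool)
        train_mask[test_idx] = False
        Xtr, Xte = X[train_mask], X[test_idx]
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        model = PNNClassifier(sigma=sigma, priors=priors).fit(Xtr, yy[train_mask])
        accs.append(100.0 * float((model.predict(Xte) == yy[test_idx]).mean()))
    return CVReport(
        fold_accuracies=accs,
        mean=float(np.mean(accs)),
        std=float(np.std(accs)),
        n_folds=n_folds,
        seed=seed,
        sigma=float(sigma),
    )
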