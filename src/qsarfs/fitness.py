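"""Subset fitness: ordinary least squares on the selected descriptors, scored by RMSE.

The wrapper selectors score a candidate subset by refitting a multiple linear
regression on the training rows restricted to the selected columns and taking
the root-mean-square error of the fitted (or leave-one-out) predictions.
Lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DescriptorTable
from .errors import ConfigurationError, DataError

__all__ = [
    "FeatureSubset",
    "MLRModel",
    "FitnessValue",
    "fit_mlr",
    "rmse",
    "evaluate_subset",
    "make_fitness_function",
]

FITNESS_MODES = ("train_rmse", "loocv_rmse")


@dataclass(frozen=True)
class FeatureSubset:
    """Boolean mask over the descriptor columns of a table."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def k(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def names(self, descriptor_names: list[str]) -> list[str]:
        return [descriptor_names[i] for i in self.indices()]


@dataclass(frozen=True)
class MLRModel:
    """Least-squares linear model: intercept + coefficients on selected columns."""

    intercept: float
    coefficients: np.ndarray

    def predict(self, X_selected: np.ndarray) -> np.ndarray:
        X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
        return self.intercept + X_selected @ self.coefficients


@dataclass(frozen=True)
class FitnessValue:
    """RMSE (minimized) with companion squared-correlation R2 over n_obs rows."""

    rmse: float
    r2: float
    n_obs: int


def fit_mlr(X_selected: np.ndarray, y: np.ndarray) -> MLRModel:
    """Ordinary least squares with intercept; minimum-norm if rank-deficient."""
    X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X_selected.shape[0] != len(y):
        raise DataError(
            f"design has {X_selected.shape[0]} rows but y has {len(y)}"
        )
    if X_selected.shape[0] < 2:
        raise DataError("need at least 2 rows to fit a regression")
    design = np.column_stack([np.ones(len(y)), X_selected])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(intercept=float(coef[0]), coefficients=coef[1:])


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """sqrt(mean squared residual)."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise DataError(
            f"length mismatch: {observed.shape[0]} observed vs {predicted.shape[0]} predicted"
        )
    if observed.size < 1:
        raise DataError("rmse of empty vectors")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def squared_pearson(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation; 1.0 on exact fits, 0.0 when degenerate."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if np.allclose(observed, predicted):
        return 1.0
    so = observed.std()
    sp = predicted.std()
    if so == 0.0 or sp == 0.0:
        return 0.0
    r = float(np.corrcoef(observed, predicted)[0, 1])
    return min(1.0, r * r)


def evaluate_subset(
    train: DescriptorTable,
    subset: FeatureSubset | np.ndarray,
    mode: str = "train_rmse",
) -> FitnessValue:
    """Score a feature subset on the training table.

    ``train_rmse`` fits on all rows and scores the same rows; ``loocv_rmse``
    refits with each row held out in turn and scores the held-out predictions.
    """
    if mode not in FITNESS_MODES:
        raise ConfigurationError(f"unknown fitness mode {mode!r}; use one of {FITNESS_MODES}")
    mask = subset.mask if isinstance(subset, FeatureSubset) else np.asarray(subset, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        raise DataError("empty feature subset")
    X_sel = train.X[:, mask]
    y = train.y
    n = len(y)
    if mode == "train_rmse":
        model = fit_mlr(X_sel, y)
        pred = model.predict(X_sel)
    else:
        if k >= n - 1:
            raise DataError(f"loocv needs k < n-1 (k={k}, n={n})")
        pred = np.empty(n)
        rows = np.arange(n)
        for i in range(n):
            keep = rows != i
            fold = fit_mlr(X_sel[keep], y[keep])
            pred[i] = fold.predict(X_sel[i : i + 1])[0]
    return FitnessValue(rmse=rmse(y, pred), r2=squared_pearson(y, pred), n_obs=n)


def make_fitness_function(train: DescriptorTable, mode: str = "train_rmse"):
    """Return a memoizing mask -> FitnessValue callable for the optimizers."""
    if mode not in FITNESS_MODES:
        raise ConfigurationError(f"unknown fitness mode {mode!r}; use one of {FITNESS_MODES}")
    cache: dict[bytes, FitnessValue] = {}

    def fitness(mask: np.ndarray) -> FitnessValue:
        key = np.ascontiguousarray(np.asarray(mask, dtype=bool)).tobytes()
        hit = cache.get(key)
        if hit is None:
            hit = evaluate_subset(train, np.frombuffer(key, dtype=bool), mode)
            cache[key] = hit
        return hit

    fitness.cache = cache  # type: ignore[attr-defined]
    return fitness
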