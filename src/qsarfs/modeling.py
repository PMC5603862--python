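"""Downstream modelling and validation of a selected descriptor subset.

Least-squares SVR with an RBF kernel (one dense linear solve), grid search
over (gamma, sigma2) by leave-one-out RMSE, external-validation statistics
(cross-validated Q2, squared correlation, through-origin determination
coefficients, rm2, regression-through-origin slopes), and leverage-based
applicability-domain assessment for a Williams plot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, DataError, NumericalError

__all__ = [
    "LSSVRModel",
    "ValidationReport",
    "ADReport",
    "rbf_kernel",
    "fit_lssvr",
    "loocv_rmse_lssvr",
    "q2_loocv_lssvr",
    "grid_search_lssvr",
    "tropsha_roy_stats",
    "leverage_threshold",
    "applicability_domain",
    "default_gamma_grid",
    "default_sigma2_grid",
]


def default_gamma_grid() -> np.ndarray:
    return np.logspace(0, 4, 25)


def default_sigma2_grid() -> np.ndarray:
    return np.logspace(-1, 4, 25)


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    """K[i, j] = exp(-||a_i - b_j||^2 / sigma2)."""
    if sigma2 <= 0:
        raise ConfigurationError(f"sigma2 must be > 0, got {sigma2}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DataError(f"column mismatch: {A.shape[1]} vs {B.shape[1]}")
    return np.exp(-cdist(A, B, "sqeuclidean") / sigma2)


@dataclass
class LSSVRModel:
    """Dual solution of least-squares SVR: one alpha per training compound."""

    alpha: np.ndarray
    bias: float
    gamma: float
    sigma2: float
    X_train: np.ndarray

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        K = rbf_kernel(X_new, self.X_train, self.sigma2)
        return K @ self.alpha + self.bias


def fit_lssvr(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> LSSVRModel:
    """Solve the LS-SVM dual block system [[0, 1^T], [1, K + I/gamma]]."""
    if gamma <= 0:
        raise ConfigurationError(f"gamma must be > 0, got {gamma}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise DataError(f"need at least 3 training rows, got {n}")
    K = rbf_kernel(X, X, sigma2)
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"singular LS-SVR system (cond={np.linalg.cond(A):.3e})"
        ) from exc
    resid = np.linalg.norm(A @ sol - rhs) / max(1.0, np.linalg.norm(rhs))
    if resid > 1e-8:
        raise NumericalError(
            f"LS-SVR solve residual {resid:.3e} > 1e-8 (cond={np.linalg.cond(A):.3e})"
        )
    return LSSVRModel(alpha=sol[1:], bias=float(sol[0]), gamma=gamma, sigma2=sigma2, X_train=X.copy())


def loocv_rmse_lssvr(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    """Leave-one-out RMSE of an LS-SVR at fixed hyperparameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise DataError("LOOCV needs at least 4 rows")
    pred = np.empty(n)
    rows = np.arange(n)
    for i in range(n):
        keep = rows != i
        model = fit_lssvr(X[keep], y[keep], gamma, sigma2)
        pred[i] = model.predict(X[i : i + 1])[0]
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def q2_loocv_lssvr(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    """Cross-validated determination coefficient 1 - PRESS/SS_total."""
    y = np.asarray(y, dtype=float).ravel()
    press = loocv_rmse_lssvr(X, y, gamma, sigma2) ** 2 * len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("constant activity: Q2 undefined")
    return 1.0 - press / ss_tot


def grid_search_lssvr(
    X: np.ndarray,
    y: np.ndarray,
    gamma_grid: np.ndarray | None = None,
    sigma2_grid: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Return the (gamma, sigma2) grid pair minimizing LOOCV RMSE.

    Ties break toward smaller gamma, then smaller sigma2.
    """
    gamma_grid = default_gamma_grid() if gamma_grid is None else np.sort(np.asarray(gamma_grid, float).ravel())
    sigma2_grid = default_sigma2_grid() if sigma2_grid is None else np.sort(np.asarray(sigma2_grid, float).ravel())
    if gamma_grid.size == 0 or sigma2_grid.size == 0:
        raise ConfigurationError("hyperparameter grids must be non-empty")
    best: tuple[float, float, float] | None = None
    for gamma in gamma_grid:
        for sigma2 in sigma2_grid:
            cv = loocv_rmse_lssvr(X, y, float(gamma), float(sigma2))
            if best is None or cv < best[2]:
                best = (float(gamma), float(sigma2), cv)
    return best


def _through_origin_r2(u: np.ndarray, v: np.ndarray) -> float:
    """Determination coefficient of u regressed on v through the origin."""
    slope = float(np.sum(u * v) / np.sum(v * v))
    ss_res = float(np.sum((u - slope * v) ** 2))
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


@dataclass
class ValidationReport:
    """External-set predictivity statistics and their pass/fail flags."""

    q2: float
    rp2: float
    r0p2: float
    r0p2_prime: float
    rm2: float
    rm2_prime: float
    k: float
    k_prime: float
    delta: float
    delta_prime: float
    clamped: bool
    passes: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q2": self.q2,
            "rp2": self.rp2,
            "r0p2": self.r0p2,
            "r0p2_prime": self.r0p2_prime,
            "rm2": self.rm2,
            "rm2_prime": self.rm2_prime,
            "k": self.k,
            "k_prime": self.k_prime,
            "delta": self.delta,
            "delta_prime": self.delta_prime,
            "clamped": self.clamped,
            "passes": dict(self.passes),
        }


def _rm2(rp2: float, r02: float) -> tuple[float, bool]:
    radicand = rp2 - r02
    clamped = radicand < 0.0
    if clamped:
        radicand = 0.0
    return rp2 * (1.0 - math.sqrt(radicand)), clamped


def tropsha_roy_stats(
    y_obs_test: np.ndarray, y_pred_test: np.ndarray, q2_train: float
) -> ValidationReport:
    """External-validation statistics for observed vs predicted activities.

    Criteria checked: cross-validated q2 > 0.5; squared correlation rp2 > 0.6;
    (rp2 - r0^2)/rp2 < 0.1 for either through-origin variant; a through-origin
    slope (k or k') within [0.85, 1.15]; and both rm2 variants > 0.5.
    """
    y = np.asarray(y_obs_test, dtype=float).ravel()
    yhat = np.asarray(y_pred_test, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise DataError("observed/predicted length mismatch")
    if y.size < 3:
        raise DataError("need at least 3 external compounds")
    if np.allclose(y, yhat):
        rp2 = 1.0
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
        rp2 = min(1.0, r * r)
    k = float(np.sum(y * yhat) / np.sum(yhat * yhat))
    k_prime = float(np.sum(y * yhat) / np.sum(y * y))
    r0p2 = _through_origin_r2(yhat, y)
    r0p2_prime = _through_origin_r2(y, yhat)
    rm2, c1 = _rm2(rp2, r0p2)
    rm2_prime, c2 = _rm2(rp2, r0p2_prime)
    delta = (rp2 - r0p2) / rp2 if rp2 > 0 else math.inf
    delta_prime = (rp2 - r0p2_prime) / rp2 if rp2 > 0 else math.inf
    passes = {
        "q2": q2_train > 0.5,
        "r2_pred": rp2 > 0.6,
        "origin_offset": (delta < 0.1) or (delta_prime < 0.1),
        "slope": (0.85 <= k <= 1.15) or (0.85 <= k_prime <= 1.15),
        "rm2": (rm2 > 0.5) and (rm2_prime > 0.5),
    }
    return ValidationReport(
        q2=float(q2_train),
        rp2=rp2,
        r0p2=r0p2,
        r0p2_prime=r0p2_prime,
        rm2=rm2,
        rm2_prime=rm2_prime,
        k=k,
        k_prime=k_prime,
        delta=delta,
        delta_prime=delta_prime,
        clamped=c1 or c2,
        passes=passes,
    )


def leverage_threshold(p: int, n: int) -> float:
    """Warning leverage h* = 3p/n."""
    if p < 1 or n < 1:
        raise ConfigurationError("p and n must be positive")
    return 3.0 * p / n


@dataclass
class ADReport:
    """Williams-plot data: leverages, threshold, standardized residuals, outliers."""

    leverages_train: np.ndarray
    leverages_test: np.ndarray
    h_star: float
    std_residuals_train: np.ndarray
    std_residuals_test: np.ndarray
    train_ids: list[str]
    test_ids: list[str]
    outliers: list[str]

    def to_dict(self) -> dict:
        return {
            "h_star": self.h_star,
            "leverages_train": [float(v) for v in self.leverages_train],
            "leverages_test": [float(v) for v in self.leverages_test],
            "std_residuals_train": [float(v) for v in self.std_residuals_train],
            "std_residuals_test": [float(v) for v in self.std_residuals_test],
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "outliers": list(self.outliers),
        }

    def to_frame(self) -> pd.DataFrame:
        """Raw Williams-plot table: (compound_id, leverage, std_residual, set)."""
        rows = []
        for cid, h, r in zip(self.train_ids, self.leverages_train, self.std_residuals_train):
            rows.append((cid, float(h), float(r), "train"))
        for cid, h, r in zip(self.test_ids, self.leverages_test, self.std_residuals_test):
            rows.append((cid, float(h), float(r), "test"))
        return pd.DataFrame(rows, columns=["compound_id", "leverage", "std_residual", "set"])


def applicability_domain(
    X_train_selected: np.ndarray,
    X_test_selected: np.ndarray,
    residuals_train: np.ndarray,
    residuals_test: np.ndarray,
    train_ids: list[str] | None = None,
    test_ids: list[str] | None = None,
) -> ADReport:
    """Leverage-based applicability domain over the p selected descriptors.

    h_i = x_i (X^T X)^-1 x_i^T over the training design (no intercept column);
    h* = 3p/n; residuals are standardized by the training-residual SD; a
    compound is flagged when |std residual| > 3 or leverage > h*.
    """
    Xtr = np.atleast_2d(np.asarray(X_train_selected, dtype=float))
    Xte = np.atleast_2d(np.asarray(X_test_selected, dtype=float))
    res_tr = np.asarray(residuals_train, dtype=float).ravel()
    res_te = np.asarray(residuals_test, dtype=float).ravel()
    n, p = Xtr.shape
    if Xte.shape[1] != p:
        raise DataError("train/test selected-descriptor counts differ")
    if len(res_tr) != n or len(res_te) != Xte.shape[0]:
        raise DataError("residual vectors misaligned with design rows")
    gram = Xtr.T @ Xtr
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("singular X^T X in leverage computation; using pseudo-inverse")
        gram_inv = np.linalg.pinv(gram)
    h_train = np.einsum("ij,jk,ik->i", Xtr, gram_inv, Xtr)
    h_test = np.einsum("ij,jk,ik->i", Xte, gram_inv, Xte)
    h_star = leverage_threshold(p, n)
    sd = float(res_tr.std(ddof=1))
    if sd == 0.0:
        sd = 1.0  # perfectly fit training set: residuals are all zero
    std_tr = res_tr / sd
    std_te = res_te / sd
    if train_ids is None:
        train_ids = [f"train_{i}" for i in range(n)]
    if test_ids is None:
        test_ids = [f"test_{i}" for i in range(Xte.shape[0])]
    outliers = [
        cid
        for cid, h, r in zip(
            list(train_ids) + list(test_ids),
            np.concatenate([h_train, h_test]),
            np.concatenate([std_tr, std_te]),
        )
        if abs(r) > 3.0 or h > h_star
    ]
    return ADReport(
        leverages_train=h_train,
        leverages_test=h_test,
        h_star=h_star,
        std_residuals_train=std_tr,
        std_residuals_test=std_te,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        outliers=outliers,
    )
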