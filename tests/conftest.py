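"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own evaluation paths:
OLS goes through explicit normal equations / pseudo-inverse, RMSE through a
per-element loop, and subset optima through exhaustive enumeration.
"""

from itertools import combinations

import numpy as np
import pytest

from qsarfs.synthetic import SyntheticSpec, generate


# ---------------------------------------------------------------------------
# independent oracles


def oracle_ols(X, y):
    """Normal-equations / pseudo-inverse OLS with intercept."""
    design = np.column_stack([np.ones(len(y)), np.atleast_2d(X)])
    return np.linalg.pinv(design.T @ design) @ design.T @ y


def oracle_rmse(observed, predicted):
    """Element-by-element RMSE sum."""
    total = 0.0
    for o, p in zip(observed, predicted):
        total += (o - p) ** 2
    return (total / len(observed)) ** 0.5


def oracle_subset_rmse(X, y, idx):
    """Training RMSE of OLS on the columns in idx (oracle path)."""
    coef = oracle_ols(X[:, list(idx)], y)
    pred = coef[0] + X[:, list(idx)] @ coef[1:]
    return oracle_rmse(y, pred)


def exhaustive_best(X, y, k):
    """Enumerate all C(p, k) subsets; return (best rmse, best index tuple)."""
    p = X.shape[1]
    best_val, best_idx = np.inf, None
    for idx in combinations(range(p), k):
        val = oracle_subset_rmse(X, y, idx)
        if val < best_val:
            best_val, best_idx = val, idx
    return best_val, best_idx


class StubRng:
    """Deterministic stand-in for a numpy Generator in operator unit tests."""

    def __init__(self, integers_values=(), choice_values=(), random_values=()):
        self._integers = list(integers_values)
        self._choices = list(choice_values)
        self._randoms = list(random_values)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def choice(self, a, size=None, replace=True):
        out = self._choices.pop(0)
        return np.asarray(out) if size is not None else out

    def random(self):
        return self._randoms.pop(0)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def planted_clean():
    """Noiseless 40 x 20 table with a 3-descriptor planted linear signal."""
    return generate(
        SyntheticSpec(n_compounds=40, n_descriptors=20, k_true=3, noise_sd=0.0, seed=11)
    )


@pytest.fixture
def planted_noisy():
    """Same shape with sd 0.1 additive noise."""
    return generate(
        SyntheticSpec(n_compounds=40, n_descriptors=20, k_true=3, noise_sd=0.1, seed=11)
    )


@pytest.fixture
def small_planted():
    """Tiny 15 x 8 noiseless table for fast exhaustive comparisons."""
    return generate(
        SyntheticSpec(n_compounds=15, n_descriptors=8, k_true=2, noise_sd=0.0, seed=5)
    )
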