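"""Synthetic descriptor tables with planted ground truth.

Descriptors are standard normal; the activity is a linear signal on a known
subset plus Gaussian noise.  Constant columns and near-duplicate correlated
pairs are planted at recorded indices so the preprocessing and selector tests
have exact expectations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import DescriptorTable, write_descriptor_table
from .errors import ConfigurationError
from .fitness import FeatureSubset

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "make_fixture_suite"]


@dataclass
class SyntheticSpec:
    n_compounds: int = 40
    n_descriptors: int = 20
    k_true: int = 3
    beta: np.ndarray | None = None
    intercept: float = 6.68  # pIC50-like scale, cosmetic only
    noise_sd: float = 0.0
    n_constant_cols: int = 0
    n_correlated_pairs: int = 0
    correlated_r: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2 or self.n_descriptors < 1:
            raise ConfigurationError("table dimensions too small")
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 < self.correlated_r < 1.0):
            raise ConfigurationError("correlated_r must be in (0, 1)")
        reserved = self.k_true + self.n_constant_cols + 2 * self.n_correlated_pairs
        if reserved > self.n_descriptors:
            raise ConfigurationError(
                f"{reserved} planted columns exceed {self.n_descriptors} descriptors"
            )
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float).ravel()
            if len(self.beta) != self.k_true:
                raise ConfigurationError("beta length must equal k_true")

    def resolved_beta(self) -> np.ndarray:
        if self.beta is not None:
            return self.beta
        return 1.0 + 0.5 * np.arange(self.k_true)


@dataclass
class GroundTruth:
    """Planted structure of one generated table."""

    subset: FeatureSubset
    true_indices: list[int]
    beta: np.ndarray
    intercept: float
    noise_sd: float
    constant_indices: list[int]
    correlated_pairs: list[tuple[int, int]]  # (base, near-duplicate)
    seed: int

    def to_dict(self) -> dict:
        return {
            "true_indices": list(self.true_indices),
            "beta": [float(b) for b in self.beta],
            "intercept": float(self.intercept),
            "noise_sd": float(self.noise_sd),
            "constant_indices": list(self.constant_indices),
            "correlated_pairs": [[int(a), int(b)] for a, b in self.correlated_pairs],
            "seed": int(self.seed),
        }


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Generate one table; same spec (and seed) always yields identical output."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    X = rng.standard_normal((n, p))
    perm = rng.permutation(p)
    pos = 0
    true_idx = sorted(int(i) for i in perm[pos : pos + spec.k_true])
    pos += spec.k_true
    const_idx = sorted(int(i) for i in perm[pos : pos + spec.n_constant_cols])
    pos += spec.n_constant_cols
    pairs = []
    for _ in range(spec.n_correlated_pairs):
        base, dup = int(perm[pos]), int(perm[pos + 1])
        pos += 2
        pairs.append((base, dup))
    for j in const_idx:
        X[:, j] = float(rng.normal())
    r = spec.correlated_r
    for base, dup in pairs:
        X[:, dup] = r * X[:, base] + np.sqrt(1 - r * r) * rng.standard_normal(n)
    beta = spec.resolved_beta()
    y = spec.intercept + X[:, true_idx] @ beta
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    ids = [f"cmpd_{i:03d}" for i in range(n)]
    names = [f"d{j:03d}" for j in range(p)]
    mask = np.zeros(p, dtype=bool)
    mask[true_idx] = True
    truth = GroundTruth(
        subset=FeatureSubset(mask),
        true_indices=true_idx,
        beta=beta,
        intercept=spec.intercept,
        noise_sd=spec.noise_sd,
        constant_indices=const_idx,
        correlated_pairs=pairs,
        seed=spec.seed,
    )
    return DescriptorTable(ids, names, X, y), truth


# Reduced-size stand-ins for the shapes of the three published descriptor
# matrices (55x221, 79x320, 45x115) the selectors were originally run on.
FIXTURE_SPECS: dict[str, SyntheticSpec] = {
    "small_a": SyntheticSpec(
        n_compounds=28, n_descriptors=44, k_true=3, noise_sd=0.0,
        n_constant_cols=2, n_correlated_pairs=2, seed=101,
    ),
    "small_b": SyntheticSpec(
        n_compounds=40, n_descriptors=64, k_true=3, noise_sd=0.1,
        n_constant_cols=3, n_correlated_pairs=3, seed=102,
    ),
    "small_c": SyntheticSpec(
        n_compounds=23, n_descriptors=30, k_true=3, noise_sd=0.05,
        n_constant_cols=1, n_correlated_pairs=1, seed=103,
    ),
}


def make_fixture_suite(out_dir) -> list[Path]:
    """Write the canonical CSV + ground-truth JSON fixture pairs.

    Regeneration with the same specs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for name, spec in FIXTURE_SPECS.items():
        table, truth = generate(spec)
        csv_path = out_dir / f"{name}.csv"
        json_path = out_dir / f"{name}.truth.json"
        write_descriptor_table(table, csv_path)
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        paths.extend([csv_path, json_path])
    return paths
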