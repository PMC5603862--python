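"""Plain genetic-algorithm feature selector.

Fixed-budget binary chromosomes (exactly k genes on), binary-tournament
selection, single-point crossover, order-based swap mutation, random repair
back to the budget, and elitism of one.  The run is bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .data import DescriptorTable
from .errors import ConfigurationError, DataError
from .fitness import FitnessValue, make_fitness_function

__all__ = [
    "Chromosome",
    "GAConfig",
    "RunResult",
    "init_population",
    "single_point_crossover",
    "order_based_mutation",
    "repair_budget",
    "ga_generation",
    "run_ga",
]


@dataclass
class Chromosome:
    """Candidate subset: boolean gene vector plus a cached fitness."""

    genes: np.ndarray
    fitness: FitnessValue | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=bool)

    @property
    def weight(self) -> int:
        return int(self.genes.sum())

    def copy(self) -> "Chromosome":
        return Chromosome(self.genes.copy(), self.fitness)


@dataclass
class GAConfig:
    k: int
    population_size: int = 100
    generations: int = 100
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ConfigurationError("crossover_rate must be in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ConfigurationError("mutation_rate must be in [0, 1]")
        if self.k < 1:
            raise ConfigurationError("feature budget k must be >= 1")


@dataclass
class RunResult:
    """Outcome of one selector run."""

    best: object
    best_fitness: FitnessValue
    convergence: list[float]
    selected_names: list[str]
    elapsed: float
    seed: int
    depths: list[int] | None = None

    @property
    def best_mask(self) -> np.ndarray:
        genes = getattr(self.best, "genes", None)
        if genes is None:
            genes = self.best.values
        return np.asarray(genes, dtype=bool)

    def to_dict(self) -> dict:
        out = {
            "selected_names": list(self.selected_names),
            "rmse": float(self.best_fitness.rmse),
            "r2": float(self.best_fitness.r2),
            "convergence": [float(v) for v in self.convergence],
            "seed": int(self.seed),
            "elapsed_seconds": float(self.elapsed),
        }
        if self.depths is not None:
            out["depths"] = [int(d) for d in self.depths]
        return out


def init_population(
    n_descriptors: int, cfg: GAConfig, rng: np.random.Generator
) -> list[Chromosome]:
    """population_size chromosomes, each with k genes on, uniform at random."""
    if cfg.k > n_descriptors:
        raise ConfigurationError(
            f"budget k={cfg.k} exceeds {n_descriptors} descriptors"
        )
    pop = []
    for _ in range(cfg.population_size):
        genes = np.zeros(n_descriptors, dtype=bool)
        genes[rng.choice(n_descriptors, size=cfg.k, replace=False)] = True
        pop.append(Chromosome(genes))
    return pop


def single_point_crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Cut at a uniform point in 1..n-1 and swap tails.

    Children are returned raw (possibly off-budget); callers repair them.
    """
    n = len(a.genes)
    if n < 2:
        raise DataError("crossover needs at least 2 genes")
    if len(b.genes) != n:
        raise DataError("parent gene lengths differ")
    c = int(rng.integers(1, n))
    child1 = Chromosome(np.concatenate([a.genes[:c], b.genes[c:]]))
    child2 = Chromosome(np.concatenate([b.genes[:c], a.genes[c:]]))
    return child1, child2


def order_based_mutation(c: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Swap the values of two distinct random positions (weight-preserving)."""
    n = len(c.genes)
    if n < 2:
        raise DataError("mutation needs at least 2 genes")
    i, j = rng.choice(n, size=2, replace=False)
    genes = c.genes.copy()
    genes[i], genes[j] = genes[j], genes[i]
    return Chromosome(genes)


def repair_budget(c: Chromosome, k: int, rng: np.random.Generator) -> Chromosome:
    """Randomly flip genes until the weight is exactly k."""
    n = len(c.genes)
    if k > n:
        raise ConfigurationError(f"budget k={k} exceeds {n} genes")
    w = c.weight
    if w == k:
        return c
    genes = c.genes.copy()
    if w > k:
        on = np.flatnonzero(genes)
        genes[rng.choice(on, size=w - k, replace=False)] = False
    else:
        off = np.flatnonzero(~genes)
        genes[rng.choice(off, size=k - w, replace=False)] = True
    return Chromosome(genes)


def _tournament(pop: list, rng: np.random.Generator):
    """Binary tournament on cached fitness: the lower-RMSE of two random picks."""
    i, j = rng.integers(0, len(pop), size=2)
    a, b = pop[i], pop[j]
    return a if a.fitness.rmse <= b.fitness.rmse else b


def ga_generation(pop, cfg: GAConfig, fitness_fn, rng: np.random.Generator):
    """One elitist generational replacement step."""
    for c in pop:
        if c.fitness is None:
            c.fitness = fitness_fn(c.genes)
    elite = min(pop, key=lambda c: c.fitness.rmse)
    new_pop = [elite.copy()]
    while len(new_pop) < cfg.population_size:
        p1 = _tournament(pop, rng)
        p2 = _tournament(pop, rng)
        if rng.random() < cfg.crossover_rate:
            c1, c2 = single_point_crossover(p1, p2, rng)
        else:
            c1, c2 = p1.copy(), p2.copy()
        for child in (c1, c2):
            if len(new_pop) >= cfg.population_size:
                break
            if rng.random() < cfg.mutation_rate:
                child = order_based_mutation(child, rng)
            child = repair_budget(child, cfg.k, rng)
            if child.fitness is None:
                child.fitness = fitness_fn(child.genes)
            new_pop.append(child)
    return new_pop


def run_ga(
    train: DescriptorTable, cfg: GAConfig, mode: str = "train_rmse"
) -> RunResult:
    """Run the GA for cfg.generations generations on a preprocessed table."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    fitness_fn = make_fitness_function(train, mode)
    pop = init_population(train.n_descriptors, cfg, rng)
    for c in pop:
        c.fitness = fitness_fn(c.genes)
    best = min(pop, key=lambda c: c.fitness.rmse).copy()
    convergence: list[float] = []
    for _ in range(cfg.generations):
        pop = ga_generation(pop, cfg, fitness_fn, rng)
        gen_best = min(pop, key=lambda c: c.fitness.rmse)
        if gen_best.fitness.rmse < best.fitness.rmse:
            best = gen_best.copy()
        convergence.append(best.fitness.rmse)
    names = [n for n, g in zip(train.descriptor_names, best.genes) if g]
    return RunResult(
        best=best,
        best_fitness=best.fitness,
        convergence=convergence,
        selected_names=names,
        elapsed=time.perf_counter() - t0,
        seed=cfg.seed,
    )
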