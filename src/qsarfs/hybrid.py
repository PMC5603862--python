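"""Hybrid GA + learning-automata selectors.

Two combinations:

* mixed — the reward/penalize update is applied to every individual inside
  each elitist GA generation; one loop counter drives both.
* sequential — a GA phase runs first and its final population (depths reset
  to the frontier) seeds a subsequent LA phase; the two phase lengths are
  independent and the convergence curves concatenate.

Genomes in the mixed loop are automata: crossover inherits value and depth
segment-wise, mutation swaps whole actions, and repair resets the depth of
any gene it changes back to the frontier.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .data import DescriptorTable
from .errors import ConfigurationError
from .fitness import make_fitness_function
from .ga import (
    Chromosome,
    GAConfig,
    RunResult,
    _tournament,
    ga_generation,
    init_population,
)
from .la import Automaton, LAConfig, init_automata, la_epoch

__all__ = [
    "HybridConfig",
    "mgala_generation",
    "run_mgala",
    "run_sgala",
]


@dataclass
class HybridConfig:
    ga: GAConfig
    la: LAConfig
    sgala_ga_generations: int = 60
    sgala_la_epochs: int = 40

    def __post_init__(self) -> None:
        if self.ga.k != self.la.k:
            raise ConfigurationError("GA and LA feature budgets differ")
        if self.sgala_ga_generations < 0 or self.sgala_la_epochs < 0:
            raise ConfigurationError("phase lengths must be >= 0")


def _crossover_automata(
    a: Automaton, b: Automaton, rng: np.random.Generator
) -> tuple[Automaton, Automaton]:
    """Single-point crossover carrying each action's value and depth together."""
    n = len(a.values)
    c = int(rng.integers(1, n))
    child1 = Automaton(
        np.concatenate([a.values[:c], b.values[c:]]),
        np.concatenate([a.depths[:c], b.depths[c:]]),
        a.memory,
    )
    child2 = Automaton(
        np.concatenate([b.values[:c], a.values[c:]]),
        np.concatenate([b.depths[:c], a.depths[c:]]),
        a.memory,
    )
    return child1, child2


def _mutate_automaton(a: Automaton, rng: np.random.Generator) -> Automaton:
    """Swap two whole actions (value and depth move together)."""
    n = len(a.values)
    i, j = rng.choice(n, size=2, replace=False)
    values = a.values.copy()
    depths = a.depths.copy()
    values[i], values[j] = values[j], values[i]
    depths[i], depths[j] = depths[j], depths[i]
    return Automaton(values, depths, a.memory)


def _repair_automaton(a: Automaton, k: int, rng: np.random.Generator) -> Automaton:
    """Enforce the budget; any gene the repair flips returns to the frontier."""
    w = a.weight
    if w == k:
        return a
    values = a.values.copy()
    depths = a.depths.copy()
    if w > k:
        on = np.flatnonzero(values)
        flip = rng.choice(on, size=w - k, replace=False)
        values[flip] = False
    else:
        off = np.flatnonzero(~values)
        flip = rng.choice(off, size=k - w, replace=False)
        values[flip] = True
    depths[flip] = 1
    return Automaton(values, depths, a.memory)


def mgala_generation(
    pop: list[Automaton],
    ga_cfg: GAConfig,
    la_cfg: LAConfig,
    fitness_fn,
    rng: np.random.Generator,
) -> list[Automaton]:
    """One mixed generation: elitist GA step over automata, then an LA update.

    The GA part draws from ``rng`` in exactly the same order as
    :func:`qsarfs.ga.ga_generation` so the two loops stay seed-aligned when
    the LA update is inert.
    """
    for a in pop:
        if a.fitness is None:
            a.fitness = fitness_fn(a.values)
    elite = min(pop, key=lambda a: a.fitness.rmse)
    new_pop = [elite.copy()]
    while len(new_pop) < ga_cfg.population_size:
        p1 = _tournament(pop, rng)
        p2 = _tournament(pop, rng)
        if rng.random() < ga_cfg.crossover_rate:
            c1, c2 = _crossover_automata(p1, p2, rng)
        else:
            c1, c2 = p1.copy(), p2.copy()
        for child in (c1, c2):
            if len(new_pop) >= ga_cfg.population_size:
                break
            if rng.random() < ga_cfg.mutation_rate:
                child = _mutate_automaton(child, rng)
            child = _repair_automaton(child, ga_cfg.k, rng)
            if child.fitness is None:
                child.fitness = fitness_fn(child.values)
            new_pop.append(child)
    la_epoch(new_pop, la_cfg, fitness_fn, rng)
    return new_pop


def run_mgala(
    train: DescriptorTable, cfg: HybridConfig, mode: str = "train_rmse"
) -> RunResult:
    """Mixed hybrid: cfg.ga.generations generations, LA update inside each."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.ga.seed)
    fitness_fn = make_fitness_function(train, mode)
    init_cfg = LAConfig(
        k=cfg.ga.k,
        population_size=cfg.ga.population_size,
        epochs=max(1, cfg.ga.generations),
        memory=cfg.la.memory,
        seed=cfg.ga.seed,
    )
    pop = init_automata(train.n_descriptors, init_cfg, rng)
    for a in pop:
        a.fitness = fitness_fn(a.values)
    best = min(pop, key=lambda a: a.fitness.rmse).copy()
    convergence: list[float] = []
    for _ in range(cfg.ga.generations):
        pop = mgala_generation(pop, cfg.ga, cfg.la, fitness_fn, rng)
        gen_best = min(pop, key=lambda a: a.fitness.rmse)
        if gen_best.fitness.rmse < best.fitness.rmse:
            best = gen_best.copy()
        convergence.append(best.fitness.rmse)
    names = [n for n, v in zip(train.descriptor_names, best.values) if v]
    return RunResult(
        best=best,
        best_fitness=best.fitness,
        convergence=convergence,
        selected_names=names,
        elapsed=time.perf_counter() - t0,
        seed=cfg.ga.seed,
        depths=[int(d) for d in best.depths],
    )


def run_sgala(
    train: DescriptorTable, cfg: HybridConfig, mode: str = "train_rmse"
) -> RunResult:
    """Sequential hybrid: GA phase, handoff at the frontier, LA phase.

    One RNG stream spans both phases, so a zero-length LA phase reproduces a
    plain GA run and a zero-length GA phase reproduces a plain LA run.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.ga.seed)
    fitness_fn = make_fitness_function(train, mode)
    n = train.n_descriptors
    pop = init_population(n, cfg.ga, rng)
    for c in pop:
        c.fitness = fitness_fn(c.genes)
    best_mask = min(pop, key=lambda c: c.fitness.rmse).genes.copy()
    best_fit = fitness_fn(best_mask)
    best_depths: list[int] | None = None
    convergence: list[float] = []
    for _ in range(cfg.sgala_ga_generations):
        pop = ga_generation(pop, cfg.ga, fitness_fn, rng)
        gen_best = min(pop, key=lambda c: c.fitness.rmse)
        if gen_best.fitness.rmse < best_fit.rmse:
            best_mask = gen_best.genes.copy()
            best_fit = gen_best.fitness
        convergence.append(best_fit.rmse)
    automata = [
        Automaton(c.genes.copy(), np.ones(n, dtype=np.int64), cfg.la.memory, c.fitness)
        for c in pop
    ]
    la_cfg = LAConfig(
        k=cfg.la.k,
        population_size=len(automata),
        epochs=max(1, cfg.sgala_la_epochs),
        memory=cfg.la.memory,
        seed=cfg.ga.seed,
    )
    for _ in range(cfg.sgala_la_epochs):
        la_epoch(automata, la_cfg, fitness_fn, rng)
        epoch_best = min(automata, key=lambda a: a.fitness.rmse)
        if epoch_best.fitness.rmse < best_fit.rmse:
            best_mask = epoch_best.values.copy()
            best_fit = epoch_best.fitness
            best_depths = [int(d) for d in epoch_best.depths]
        convergence.append(best_fit.rmse)
    best = Chromosome(best_mask, best_fit)
    names = [nm for nm, g in zip(train.descriptor_names, best_mask) if g]
    return RunResult(
        best=best,
        best_fitness=best_fit,
        convergence=convergence,
        selected_names=names,
        elapsed=time.perf_counter() - t0,
        seed=cfg.ga.seed,
        depths=best_depths,
    )
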