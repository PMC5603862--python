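"""Object-migration (Tsetlin-style) learning-automata feature selector.

Each descriptor is an action carrying a value bit (selected or not) and a
memory depth in 1..N.  Depth 1 is the frontier.  Each epoch probes one random
action per automaton: the probe flips the action (with a budget-compensating
opposite flip) in a throwaway trial and compares RMSE.  If the current state
is at least as good (S1 <= S2) the action is rewarded and moves inward;
otherwise it is penalized — moved toward the frontier, or flipped once it is
already there.  Probing never mutates the automaton.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from .data import DescriptorTable
from .errors import ConfigurationError
from .fitness import FitnessValue, make_fitness_function
from .ga import RunResult, _tournament  # noqa: F401  (tournament reused by hybrid)

__all__ = [
    "ActionState",
    "Automaton",
    "LAConfig",
    "ProbeOutcome",
    "init_automata",
    "probe_action",
    "reward",
    "penalize",
    "la_epoch",
    "run_la",
]


@dataclass(frozen=True)
class ActionState:
    """One action: selection bit plus memory depth (1 = frontier)."""

    value: bool
    depth: int


@dataclass
class Automaton:
    """Vector of actions with a shared memory bound and a cached fitness."""

    values: np.ndarray
    depths: np.ndarray
    memory: int
    fitness: FitnessValue | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.memory < 1:
            raise ConfigurationError("memory depth bound must be >= 1")
        if self.depths.shape != self.values.shape:
            raise ConfigurationError("values and depths must be aligned")

    @property
    def weight(self) -> int:
        return int(self.values.sum())

    def action(self, j: int) -> ActionState:
        return ActionState(bool(self.values[j]), int(self.depths[j]))

    def copy(self) -> "Automaton":
        return Automaton(self.values.copy(), self.depths.copy(), self.memory, self.fitness)


@dataclass
class LAConfig:
    k: int
    population_size: int = 100
    epochs: int = 100
    memory: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ConfigurationError("population_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.memory < 1:
            raise ConfigurationError("memory must be >= 1")
        if self.k < 1:
            raise ConfigurationError("feature budget k must be >= 1")


@dataclass(frozen=True)
class ProbeOutcome:
    """Environment response for one probed action.

    beta = 0 (reward) iff s1 <= s2, where s1 is the automaton's RMSE and s2
    the RMSE of the budget-compensated flipped trial.  ``partner`` is the
    compensating action flipped in the trial (None when no opposite-valued
    action exists).
    """

    s1: float
    s2: float
    beta: int
    partner: int | None


def init_automata(
    n_descriptors: int, cfg: LAConfig, rng: np.random.Generator
) -> list[Automaton]:
    """Random automata: k actions on, every depth at the frontier."""
    if cfg.k > n_descriptors:
        raise ConfigurationError(
            f"budget k={cfg.k} exceeds {n_descriptors} descriptors"
        )
    pop = []
    for _ in range(cfg.population_size):
        values = np.zeros(n_descriptors, dtype=bool)
        values[rng.choice(n_descriptors, size=cfg.k, replace=False)] = True
        pop.append(Automaton(values, np.ones(n_descriptors, dtype=np.int64), cfg.memory))
    return pop


def _choose_partner(a: Automaton, j: int, rng: np.random.Generator) -> int | None:
    """Opposite-valued action at minimum depth (frontier preferred), uniform."""
    opposite = np.flatnonzero(a.values != a.values[j])
    if opposite.size == 0:
        return None
    depths = a.depths[opposite]
    candidates = opposite[depths == depths.min()]
    return int(rng.choice(candidates))


def probe_action(
    a: Automaton, j: int, fitness_fn, rng: np.random.Generator
) -> ProbeOutcome:
    """Evaluate the flip-trial for action j without mutating the automaton."""
    if a.fitness is None:
        a.fitness = fitness_fn(a.values)
    s1 = a.fitness.rmse
    partner = _choose_partner(a, j, rng)
    if partner is None:
        s2 = math.inf
    else:
        trial = a.values.copy()
        trial[j] = not trial[j]
        trial[partner] = not trial[partner]
        s2 = fitness_fn(trial).rmse
    beta = 0 if s1 <= s2 else 1
    return ProbeOutcome(s1=s1, s2=s2, beta=beta, partner=partner)


def reward(a: Automaton, j: int) -> Automaton:
    """Move action j one state inward (saturating at the memory bound)."""
    a.depths[j] = min(a.memory, int(a.depths[j]) + 1)
    return a


def penalize(
    a: Automaton,
    j: int,
    rng: np.random.Generator,
    partner: int | None = None,
) -> Automaton:
    """Move action j one state toward the frontier; flip it if already there.

    A frontier flip also flips one opposite-valued compensating action
    (``partner`` if given, else drawn as in the probe) so the selected-action
    count stays at the budget; both flipped actions return to depth 1.
    """
    if int(a.depths[j]) > 1:
        a.depths[j] -= 1
        return a
    if partner is None:
        partner = _choose_partner(a, j, rng)
    if partner is None:
        return a  # no opposite-valued action: flipping would break the budget
    a.values[j] = not a.values[j]
    a.values[partner] = not a.values[partner]
    a.depths[j] = 1
    a.depths[partner] = 1
    a.fitness = None
    return a


def la_epoch(
    pop: list[Automaton], cfg: LAConfig, fitness_fn, rng: np.random.Generator
) -> list[Automaton]:
    """Probe one random action per automaton and reward or penalize it."""
    for a in pop:
        if a.fitness is None:
            a.fitness = fitness_fn(a.values)
        j = int(rng.integers(len(a.values)))
        outcome = probe_action(a, j, fitness_fn, rng)
        if outcome.beta == 0:
            reward(a, j)
        else:
            penalize(a, j, rng, partner=outcome.partner)
            if a.fitness is None:
                a.fitness = fitness_fn(a.values)
    return pop


def run_la(
    train: DescriptorTable, cfg: LAConfig, mode: str = "train_rmse"
) -> RunResult:
    """Run the learning-automata selector for cfg.epochs epochs."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    fitness_fn = make_fitness_function(train, mode)
    pop = init_automata(train.n_descriptors, cfg, rng)
    for a in pop:
        a.fitness = fitness_fn(a.values)
    best = min(pop, key=lambda a: a.fitness.rmse).copy()
    convergence: list[float] = []
    for _ in range(cfg.epochs):
        la_epoch(pop, cfg, fitness_fn, rng)
        epoch_best = min(pop, key=lambda a: a.fitness.rmse)
        if epoch_best.fitness.rmse < best.fitness.rmse:
            best = epoch_best.copy()
        convergence.append(best.fitness.rmse)
    names = [n for n, v in zip(train.descriptor_names, best.values) if v]
    return RunResult(
        best=best,
        best_fitness=best.fitness,
        convergence=convergence,
        selected_names=names,
        elapsed=time.perf_counter() - t0,
        seed=cfg.seed,
        depths=[int(d) for d in best.depths],
    )
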