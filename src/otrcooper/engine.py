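"""Elitist genetic-algorithm loop: fitness, roulette selection, procedure mix, termination.

The engine is generic over a *constructor toolkit* — an object that knows how
to create and vary feasible individuals of one part kind (head or body) over
a fixed stave pool — so the same loop drives head construction, body
construction, and (by degenerate configuration) the Monte-Carlo baseline.

Fitness is the negative absolute OTR error, ``-(|target - element OTR|)``,
so 0 is a perfect element. Parents are drawn by roulette-wheel selection
with probabilities ``exp(-f_n / min f) / sum(...)`` over the (non-positive)
fitness values, which gives the best individual weight e^0 = 1 and the worst
weight e^-1.

Each generation carries the single best individual over unchanged (elitism)
and fills the remaining slots by sampling one of five procedures per slot:
generating a new solution, reapplying a roulette-selected solution, mutation,
internal crossing (heads only) or external crossing.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from .errors import InfeasiblePoolError

#: Canonical procedure order; probability vectors follow this order.
PROCEDURES = ("new", "reapply", "mutate", "internal_cross", "external_cross")

#: Per-generation procedure probabilities for head construction.
HEAD_PROCEDURES = {
    "new": 0.40, "reapply": 0.12, "mutate": 0.21,
    "internal_cross": 0.06, "external_cross": 0.21,
}

#: Per-generation procedure probabilities for body construction. Internal
#: crossing is absent for bodies because stave order does not affect a body's OTR.
BODY_PROCEDURES = {
    "new": 0.40, "reapply": 0.134, "mutate": 0.233,
    "internal_cross": 0.0, "external_cross": 0.233,
}

#: Degenerate mix implementing the Monte-Carlo baseline: every non-elite slot
#: is a brand-new random feasible solution.
MC_PROCEDURES = {
    "new": 1.0, "reapply": 0.0, "mutate": 0.0,
    "internal_cross": 0.0, "external_cross": 0.0,
}


class ConstructorToolkit(Protocol):
    """What the engine needs from a part-specific constructor."""

    def new(self, rng: np.random.Generator): ...

    def mutate(self, individual, rng: np.random.Generator): ...

    def internal_cross(self, individual, rng: np.random.Generator): ...

    def external_cross(self, a, b, rng: np.random.Generator): ...

    def otr(self, individual) -> float: ...


@dataclass
class GAConfig:
    """Configuration of one evolve() call.

    ``procedures`` maps procedure name to probability and must sum to 1;
    defaults differ per part (:data:`HEAD_PROCEDURES` / :data:`BODY_PROCEDURES`).
    ``tolerance`` is the absolute OTR error below which the run stops
    (hPa/h). Budgets: ``max_generations`` and/or ``max_wall_seconds`` may be
    set; whichever is reached first ends the run. The generation budget is
    the default because it is reproducible across machines.
    """

    target_otr: float
    procedures: dict[str, float] = field(default_factory=lambda: dict(BODY_PROCEDURES))
    population_size: int = 10
    elite_count: int = 1
    tolerance: float = 1e-6
    max_generations: int | None = 5000
    max_wall_seconds: float | None = None
    seed: int | None = None

    def __post_init__(self):
        unknown = set(self.procedures) - set(PROCEDURES)
        if unknown:
            raise ValueError(f"unknown procedures {sorted(unknown)}")
        total = sum(self.procedures.get(p, 0.0) for p in PROCEDURES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"procedure probabilities must sum to 1, got {total}")
        if any(v < 0 for v in self.procedures.values()):
            raise ValueError("procedure probabilities must be non-negative")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not (1 <= self.elite_count < self.population_size):
            raise ValueError("elite_count must be in [1, population_size)")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.max_generations is None and self.max_wall_seconds is None:
            raise ValueError("at least one of max_generations / max_wall_seconds must be set")

    def for_head(self) -> "GAConfig":
        return replace(self, procedures=dict(HEAD_PROCEDURES))

    def for_body(self) -> "GAConfig":
        return replace(self, procedures=dict(BODY_PROCEDURES))


@dataclass
class EvolutionTrace:
    """Per-run bookkeeping: best fitness per generation and why the run ended."""

    best_per_generation: list[float]
    termination: str  # "tolerance_met" or "budget_exhausted"
    generations: int
    elapsed_seconds: float
    best_fitness: float
    best_otr: float


def fitness(element_otr: float, target_otr: float) -> float:
    """Negative absolute OTR error; 0 iff the element hits the target exactly."""
    return -abs(target_otr - element_otr)


def selection_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Roulette probabilities from non-positive fitness values.

    p_n = exp(-f_n / min f) / sum over the population. When every fitness is
    exactly 0 the expression is undefined (division by min f = 0) and any
    individual is perfect, so the probabilities degrade to uniform.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("fitness list is empty")
    if np.any(f > 0):
        raise ValueError("fitness values must be <= 0")
    fmin = f.min()
    if fmin == 0.0:
        return np.full(f.size, 1.0 / f.size)
    e = np.exp(-f / fmin)
    return e / e.sum()


def roulette_select(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one index with the given probabilities."""
    cum = np.cumsum(probabilities)
    return int(min(np.searchsorted(cum, rng.random() * cum[-1], side="right"),
                   len(probabilities) - 1))


def _roulette_pair(probabilities: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """Two roulette draws without replacement (crossing parents)."""
    i = roulette_select(probabilities, rng)
    rest = probabilities.copy()
    rest[i] = 0.0
    total = rest.sum()
    if total <= 0.0:
        j = i
        while j == i:
            j = int(rng.integers(len(probabilities)))
        return i, j
    return i, roulette_select(rest / total, rng)


def evolve(toolkit: ConstructorToolkit, config: GAConfig,
           rng: np.random.Generator | None = None):
    """Run the elitist GA and return ``(best_individual, EvolutionTrace)``.

    The best-ever individual is returned even when the run ends on budget.
    One RNG stream drives the whole run: per non-elite slot, one uniform
    draw picks the procedure, then the procedure's own draws follow in
    construction order. A ``new`` procedure that fails mid-run (the pool can
    no longer seed a fresh feasible element) falls back to reapplying a
    roulette-selected individual so the slot is always filled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    target = config.target_otr
    proc_cum = np.cumsum([config.procedures.get(p, 0.0) for p in PROCEDURES])

    population = [toolkit.new(rng) for _ in range(config.population_size)]
    fits = [fitness(toolkit.otr(ind), target) for ind in population]

    best_i = max(range(len(fits)), key=fits.__getitem__)
    best_ind, best_fit = population[best_i], fits[best_i]
    history = [best_fit]

    start = time.perf_counter()
    generations = 0
    termination = "budget_exhausted"
    while True:
        if config.max_generations is not None and generations >= config.max_generations:
            break
        if (config.max_wall_seconds is not None
                and time.perf_counter() - start >= config.max_wall_seconds):
            break

        probs = selection_probabilities(fits)
        new_pop = [best_ind]
        new_fits = [best_fit]
        for _ in range(config.population_size - 1):
            u = rng.random()
            proc = PROCEDURES[int(min(np.searchsorted(proc_cum, u, side="right"),
                                      len(PROCEDURES) - 1))]
            if proc == "new":
                try:
                    child = toolkit.new(rng)
                except InfeasiblePoolError:
                    child = population[roulette_select(probs, rng)]
            elif proc == "reapply":
                child = population[roulette_select(probs, rng)]
            elif proc == "mutate":
                child = toolkit.mutate(population[roulette_select(probs, rng)], rng)
            elif proc == "internal_cross":
                child = toolkit.internal_cross(population[roulette_select(probs, rng)], rng)
            else:  # external_cross
                i, j = _roulette_pair(probs, rng)
                child = toolkit.external_cross(population[i], population[j], rng)
            new_pop.append(child)
            new_fits.append(fitness(toolkit.otr(child), target))

        population, fits = new_pop, new_fits
        generations += 1
        gen_best = max(range(len(fits)), key=fits.__getitem__)
        if fits[gen_best] > best_fit:
            best_ind, best_fit = population[gen_best], fits[gen_best]
        history.append(best_fit)
        if -best_fit < config.tolerance:
            termination = "tolerance_met"
            break

    elapsed = time.perf_counter() - start
    trace = EvolutionTrace(
        best_per_generation=history,
        termination=termination,
        generations=generations,
        elapsed_seconds=elapsed,
        best_fitness=best_fit,
        best_otr=toolkit.otr(best_ind),
    )
    return best_ind, trace
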