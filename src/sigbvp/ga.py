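"""Real-coded genetic algorithm over the bounded 3n-dimensional parameter box.

Operators follow the classical real-coded toolbox repertoire: stochastic
uniform (SUS) selection on rank-scaled expectations, heuristic crossover
(child placed on the parent line, biased past the fitter parent), and an
adaptive-feasible mutation whose step scale quadruples after an improving
generation and shrinks fourfold otherwise.  Elitism makes the best-fitness
trace non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .fitness import FitnessSpec, fitness_population
from .problems import SingularBVP

__all__ = [
    "GAConfig",
    "Population",
    "init_population",
    "select_stochastic_uniform",
    "crossover_heuristic",
    "mutate_adaptive_feasible",
    "run_ga",
    "GARun",
]


@dataclass(frozen=True)
class GAConfig:
    """Hyper-parameters of the genetic algorithm.

    Defaults are the benchmark settings: 240 individuals of length 30
    (ten sigmoid triples), 2000 generations, genes bounded in [-15, 15],
    heuristic crossover with ratio 1.2 on 80% of the non-elite slots,
    adaptive-feasible mutation on the rest, two elites, and a stall stop
    when 50 consecutive generations improve by less than 1e-18.
    """

    population_size: int = 240
    chromosome_length: int = 30
    generations: int = 2000
    lower_bound: float = -15.0
    upper_bound: float = 15.0
    crossover_ratio: float = 1.2
    crossover_fraction: float = 0.8
    mutation_scale: float = 1.0
    elite_count: int = 2
    function_tolerance: float = 1e-18
    stall_generations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be in [0, population_size)")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be below upper_bound")
        if not 0.0 < self.crossover_fraction < 1.0:
            raise ValueError("crossover_fraction must lie in (0, 1)")


@dataclass
class Population:
    """Parameter vectors with their total fitnesses at one generation."""

    individuals: np.ndarray  # (pop, L)
    fitnesses: np.ndarray  # (pop,)
    generation: int = 0

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals, dtype=float)
        self.fitnesses = np.asarray(self.fitnesses, dtype=float)
        if self.individuals.shape[0] != self.fitnesses.shape[0]:
            raise ValueError("individuals and fitnesses must be parallel")

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitnesses))


def init_population(cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random individuals in the search box, (pop, L)."""
    return rng.uniform(cfg.lower_bound, cfg.upper_bound,
                       size=(cfg.population_size, cfg.chromosome_length))


def _rank_expectations(fitnesses: np.ndarray) -> np.ndarray:
    """Rank-based selection expectations, 1/sqrt(rank), best rank = 1.

    Raw fitness spans many orders of magnitude, so proportional selection
    on raw values would collapse onto one individual; rank scaling keeps
    the pressure bounded.  Infinite-fitness individuals get expectation 0.
    """
    order = np.argsort(fitnesses, kind="stable")
    expect = np.zeros(fitnesses.size)
    finite = np.isfinite(fitnesses[order])
    ranks = np.arange(1, fitnesses.size + 1, dtype=float)
    expect[order[finite]] = 1.0 / np.sqrt(ranks[: int(finite.sum())])
    return expect


def _sus_indices(fitnesses: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    expect = _rank_expectations(fitnesses)
    total = expect.sum()
    if total <= 0.0:
        raise ValueError("cannot select from a population with no finite fitness")
    cum = np.cumsum(expect)
    step = total / k
    points = (rng.uniform(0.0, step) + step * np.arange(k)) % total
    idx = np.searchsorted(cum, points, side="right")
    return np.minimum(idx, expect.size - 1)


def select_stochastic_uniform(pop: Population, k: int, rng: np.random.Generator) -> np.ndarray:
    """SUS: k equally spaced pointers over the cumulative expectation line.

    Returns the selected individuals as a (k, L) array.  Expectations are
    rank-scaled (lower fitness = better); a single uniform spin gives the
    low-variance proportional sample.
    """
    return pop.individuals[_sus_indices(pop.fitnesses, k, rng)]


def crossover_heuristic(p1: np.ndarray, p2: np.ndarray, R: float,
                        rng: np.random.Generator,
                        bounds: Tuple[float, float] = (-15.0, 15.0)) -> np.ndarray:
    """Child = p2 + r*R*(p1 - p2), r ~ U(0,1); p1 must be the fitter parent.

    The child moves from the worse parent toward and (for R > 1) beyond the
    better one, then is clipped to the search box.
    """
    r = rng.uniform()
    child = p2 + r * R * (p1 - p2)
    return np.clip(child, bounds[0], bounds[1])


def mutate_adaptive_feasible(v: np.ndarray, scale: float,
                             bounds: Tuple[float, float],
                             rng: np.random.Generator) -> np.ndarray:
    """Random feasible step with per-gene magnitude scale*U(0,1)*(ub-lb)/100."""
    lo, hi = bounds
    mag = scale * rng.uniform(size=np.shape(v)) * (hi - lo) / 100.0
    sign = rng.choice([-1.0, 1.0], size=np.shape(v))
    return np.clip(np.asarray(v, dtype=float) + sign * mag, lo, hi)


@dataclass
class GARun:
    """Outcome of one GA run: best vector, its fitness, and the trace."""

    best: np.ndarray
    best_fitness: float
    trace: List[Tuple[int, float]] = field(default_factory=list)
    generations_run: int = 0


def run_ga(problem: Optional[SingularBVP], spec: Optional[FitnessSpec],
           cfg: GAConfig, rng: Optional[np.random.Generator] = None,
           objective: Optional[Callable[[np.ndarray], np.ndarray]] = None) -> GARun:
    """Evolve the population and return the best individual found.

    ``objective`` (a callable mapping a (P, L) matrix to P totals) overrides
    the collocation fitness; it exists so the optimizer can be exercised on
    analytic test functions.  With the default objective the problem's
    fitness is evaluated vectorized over the whole population.
    """
    if objective is None:
        if problem is None:
            raise ValueError("either a problem or an explicit objective is required")
        n = cfg.chromosome_length // 3
        if 3 * n != cfg.chromosome_length:
            raise ValueError("chromosome_length must be a multiple of 3")
        spec = spec if spec is not None else FitnessSpec()

        def objective(V: np.ndarray) -> np.ndarray:
            return fitness_population(problem, V, n, spec)

    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.lower_bound, cfg.upper_bound

    V = init_population(cfg, rng)
    fit = np.asarray(objective(V), dtype=float)
    pop = Population(V, fit, generation=0)
    best_val = float(fit.min())
    best_vec = V[int(np.argmin(fit))].copy()
    trace: List[Tuple[int, float]] = [(0, best_val)]
    scale = cfg.mutation_scale

    n_rest = cfg.population_size - cfg.elite_count
    n_cross = int(round(cfg.crossover_fraction * n_rest))
    n_mut = n_rest - n_cross

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(pop.fitnesses, kind="stable")
        elite = pop.individuals[order[: cfg.elite_count]]

        pick = _sus_indices(pop.fitnesses, 2 * n_cross + n_mut, rng)
        rng.shuffle(pick)
        parents = pop.individuals[pick]

        children = np.empty((n_rest, cfg.chromosome_length))
        if n_cross:
            pa = parents[:n_cross]
            pb = parents[n_cross : 2 * n_cross]
            fa = pop.fitnesses[pick[:n_cross]]
            fb = pop.fitnesses[pick[n_cross : 2 * n_cross]]
            swap = fa > fb  # ensure pa holds the fitter parent
            pa, pb = np.where(swap[:, None], pb, pa), np.where(swap[:, None], pa, pb)
            r = rng.uniform(size=(n_cross, 1))
            children[:n_cross] = np.clip(pb + r * cfg.crossover_ratio * (pa - pb), lo, hi)
        if n_mut:
            base = parents[2 * n_cross :]
            mag = scale * rng.uniform(size=base.shape) * (hi - lo) / 100.0
            sign = rng.choice([-1.0, 1.0], size=base.shape)
            children[n_cross:] = np.clip(base + sign * mag, lo, hi)

        V = np.vstack([elite, children])
        fit = np.asarray(objective(V), dtype=float)
        pop = Population(V, fit, generation=gen)

        gen_best = float(fit.min())
        improved = gen_best < best_val - 0.0
        if improved:
            best_val = gen_best
            best_vec = V[int(np.argmin(fit))].copy()
        scale = min(1.0, scale * 4.0) if improved else max(1e-6, scale * 0.25)
        trace.append((gen, best_val))

        if gen >= cfg.stall_generations:
            past = trace[gen - cfg.stall_generations][1]
            if past - best_val < cfg.function_tolerance:
                break

    return GARun(best=best_vec, best_fitness=best_val, trace=trace,
                 generations_run=trace[-1][0])
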