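"""Driver: hybrid solve pipelines and the model-level interface.

Five method labels are supported:

* ``GA`` — genetic algorithm alone;
* ``IPA`` / ``ASA`` — interior-point or active-set refinement from a random
  feasible start (the standalone local searches);
* ``GA-IPA`` / ``GA-ASA`` — the hybrids: the GA's best vector is fed to the
  refiner for fine tuning.

With ``restarts > 1`` the whole pipeline is repeated with derived seeds
(base + k) and the winner is chosen by total fitness — the exact solution
is never consulted during optimization.

:class:`SigmoidCollocationModel` wraps the same pipeline in a fit/results
shape: build the model from a problem, call :meth:`fit`, inspect the
returned :class:`~sigbvp.report.SolveResult`.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .basis import unpack
from .fitness import FitnessSpec, FitnessValue, eps1, eps2
from .ga import GAConfig, run_ga
from .problems import SingularBVP, get_problem
from .refine import RefineConfig, refine
from .report import SolveResult

__all__ = ["solve", "SigmoidCollocationModel"]

_GA_METHODS = {"GA", "GA-IPA", "GA-ASA"}
_REFINE_OF = {"IPA": "interior-point", "ASA": "active-set",
              "GA-IPA": "interior-point", "GA-ASA": "active-set"}


def _solve_once(problem: SingularBVP, method: str, spec: FitnessSpec,
                ga_cfg: GAConfig, refine_cfg: RefineConfig, seed: int) -> SolveResult:
    rng = np.random.default_rng(seed)
    n = ga_cfg.chromosome_length // 3
    trace = []

    if method in _GA_METHODS:
        ga_run = run_ga(problem, spec, ga_cfg, rng=rng)
        start = ga_run.best
        trace = list(ga_run.trace)
    else:
        start = rng.uniform(ga_cfg.lower_bound, ga_cfg.upper_bound, ga_cfg.chromosome_length)

    if method in _REFINE_OF:
        cfg = replace(refine_cfg, method=_REFINE_OF[method])
        run = refine(problem, spec, start, cfg, rng=rng)
        offset = trace[-1][0] if trace else 0
        if trace:
            trace.append((offset + max(run.n_iterations, 1), run.fitness.total))
        else:
            trace = [(0, None), (max(run.n_iterations, 1), run.fitness.total)]
            e0 = unpack(start, n)
            trace[0] = (0, eps1(problem, e0, spec) + eps2(problem, e0, spec.bc_weight))
        best, fv = run.x, run.fitness
    else:
        e = unpack(start, n)
        best = start
        fv = FitnessValue(eps1(problem, e, spec), eps2(problem, e, spec.bc_weight))

    return SolveResult(best_params=best, best_fitness=fv, trace=trace,
                       method=method, seed=seed, restarts=1,
                       problem=problem, spec=spec,
                       meta={"ga": ga_cfg, "refine": refine_cfg})


def solve(problem: SingularBVP, method: str = "GA-IPA",
          spec: Optional[FitnessSpec] = None,
          ga_cfg: Optional[GAConfig] = None,
          refine_cfg: Optional[RefineConfig] = None,
          seed: int = 0, restarts: int = 1) -> SolveResult:
    """Run one method on one problem; best-of-``restarts`` by total fitness."""
    method = method.upper()
    if method not in {"GA", "IPA", "ASA"} | set(_REFINE_OF):
        raise ValueError(f"unknown method {method!r}; choose from GA, IPA, ASA, GA-IPA, GA-ASA")
    if restarts < 1:
        raise ValueError("restarts must be at least 1")
    spec = spec if spec is not None else FitnessSpec()
    ga_cfg = ga_cfg if ga_cfg is not None else GAConfig(seed=seed)
    refine_cfg = refine_cfg if refine_cfg is not None else RefineConfig()

    winner: Optional[SolveResult] = None
    for k in range(restarts):
        res = _solve_once(problem, method, spec, ga_cfg, refine_cfg, seed + k)
        if winner is None or res.best_fitness.total < winner.best_fitness.total:
            winner = res
    winner.seed = seed
    winner.restarts = restarts
    return winner


class SigmoidCollocationModel:
    """Log-sigmoid collocation model of a singular BVP.

    Parameters
    ----------
    problem : SingularBVP
        The boundary-value problem to approximate.
    n_basis : int
        Number of sigmoid basis triples; the searched parameter vector has
        length ``3 * n_basis``.
    spec : FitnessSpec, optional
        Collocation grid and boundary weight; defaults to the 11-point
        closed equispaced grid with the singular-limit rule at x = 0.

    Examples
    --------
    >>> from sigbvp import SigmoidCollocationModel
    >>> model = SigmoidCollocationModel.from_name("example1")
    >>> res = model.fit(method="GA-IPA", seed=1)       # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, problem: SingularBVP, n_basis: int = 10,
                 spec: Optional[FitnessSpec] = None) -> None:
        if n_basis < 1:
            raise ValueError("n_basis must be positive")
        self.problem = problem
        self.n_basis = int(n_basis)
        self.spec = spec if spec is not None else FitnessSpec()

    @classmethod
    def from_name(cls, name: str, m: Optional[float] = None, **kwargs) -> "SigmoidCollocationModel":
        return cls(get_problem(name, m), **kwargs)

    def loss(self, params: np.ndarray) -> FitnessValue:
        """Fitness triple of an arbitrary parameter vector."""
        e = unpack(params, self.n_basis)
        return FitnessValue(eps1(self.problem, e, self.spec),
                            eps2(self.problem, e, self.spec.bc_weight))

    def fit(self, method: str = "GA-IPA", seed: int = 0, restarts: int = 1,
            ga_cfg: Optional[GAConfig] = None,
            refine_cfg: Optional[RefineConfig] = None) -> SolveResult:
        """Optimize the expansion parameters; returns a results object."""
        if ga_cfg is None:
            ga_cfg = GAConfig(chromosome_length=3 * self.n_basis, seed=seed)
        elif ga_cfg.chromosome_length != 3 * self.n_basis:
            raise ValueError("ga_cfg.chromosome_length must equal 3 * n_basis")
        return solve(self.problem, method=method, spec=self.spec,
                     ga_cfg=ga_cfg, refine_cfg=refine_cfg,
                     seed=seed, restarts=restarts)
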