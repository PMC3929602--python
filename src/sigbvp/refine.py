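"""Bound-constrained local refinement of the collocation fitness.

Two refiners mirror the hybrid pipeline's second stage: an interior-point
strategy (scipy's trust-constr, which handles the box through a barrier /
trust-region interior method) and an active-set/SQP strategy (SLSQP).
Both are adapters over :func:`scipy.optimize.minimize`: the contract here
is bounds, iteration/evaluation caps, the gradient source, and the
guarantee that the returned point is never worse than the start.

Gradients are analytic by default (the fitness is exactly differentiable
through the sigmoid chain); central differences are the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import Bounds, minimize

from .fitness import FitnessSpec, FitnessValue, eps1, eps2, fitness_and_grad, fitness_population
from .basis import unpack
from .problems import SingularBVP

__all__ = ["RefineConfig", "numeric_gradient", "refine", "RefineRun"]

_METHODS = {"interior-point": "trust-constr", "active-set": "SLSQP"}


@dataclass(frozen=True)
class RefineConfig:
    """Settings of the local refiner.

    ``tolerance`` is passed through as printed in the benchmark settings
    (1e-18) but is effectively floored near machine epsilon by the
    underlying solvers.  ``gradient`` selects the exact chain-rule gradient
    ("analytic") or central differences ("central") with step ``fd_step``.
    """

    method: str = "interior-point"
    max_iterations: Optional[int] = None  # default: 1000 IPA, 400 ASA
    max_function_evaluations: int = 150000
    tolerance: float = 1e-18
    gradient: str = "analytic"
    fd_step: float = 1e-6
    lower_bound: float = -15.0
    upper_bound: float = 15.0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {tuple(_METHODS)}")
        if self.gradient not in ("analytic", "central"):
            raise ValueError("gradient must be 'analytic' or 'central'")
        if self.tolerance <= 0 or self.fd_step <= 0:
            raise ValueError("tolerance and fd_step must be positive")
        if self.max_iterations is not None and self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")

    @property
    def iterations(self) -> int:
        if self.max_iterations is not None:
            return self.max_iterations
        return 1000 if self.method == "interior-point" else 400


def numeric_gradient(f: Callable[[np.ndarray], float], v: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient, per coordinate (f(v+h e_i) - f(v-h e_i))/(2h)."""
    v = np.asarray(v, dtype=float)
    g = np.empty(v.size)
    for i in range(v.size):
        step = np.zeros(v.size)
        step[i] = h
        g[i] = (f(v + step) - f(v - step)) / (2.0 * h)
    return g


@dataclass
class RefineRun:
    """Outcome of one refinement: point, fitness triple, iteration count."""

    x: np.ndarray
    fitness: FitnessValue
    n_iterations: int
    n_evaluations: int


def refine(problem: SingularBVP, spec: Optional[FitnessSpec], start: np.ndarray,
           cfg: Optional[RefineConfig] = None,
           rng: Optional[np.random.Generator] = None) -> RefineRun:
    """Locally minimize the fitness from ``start`` within the search box.

    The returned point always satisfies fitness(out) <= fitness(start): if
    the solver terminates on a worse point, the start is returned.  A
    non-finite fitness at the start triggers one small feasible
    perturbation before giving up.
    """
    cfg = cfg if cfg is not None else RefineConfig()
    spec = spec if spec is not None else FitnessSpec()
    start = np.asarray(start, dtype=float).ravel()
    n = start.size // 3
    if 3 * n != start.size:
        raise ValueError("start vector length must be a multiple of 3")
    lo, hi = cfg.lower_bound, cfg.upper_bound
    if np.any(start < lo) or np.any(start > hi):
        raise ValueError("start point must lie within the bounds")

    def f_only(v: np.ndarray) -> float:
        return float(fitness_population(problem, v, n, spec)[0])

    counter = {"nfev": 0}
    best = {"x": None, "f": np.inf}

    class _BudgetExceeded(Exception):
        pass

    def _track(v: np.ndarray, val: float) -> None:
        counter["nfev"] += 1
        if np.isfinite(val) and val < best["f"]:
            best["x"], best["f"] = np.array(v, dtype=float), val
        if counter["nfev"] > cfg.max_function_evaluations:
            raise _BudgetExceeded

    use_analytic = cfg.gradient == "analytic" and problem.rhs_dy is not None
    if use_analytic:
        def f_and_g(v):
            val, g = fitness_and_grad(problem, v, n, spec)
            _track(v, val)
            if not np.isfinite(val):
                return 1e300, np.zeros_like(v)
            return val, g
        fun, jac = f_and_g, True
    else:
        def fun(v):
            val = f_only(v)
            _track(v, val)
            return val if np.isfinite(val) else 1e300
        jac = None

    f0 = f_only(start)
    if not np.isfinite(f0):
        rng = rng if rng is not None else np.random.default_rng(0)
        start = np.clip(start + rng.uniform(-0.01, 0.01, start.size), lo, hi)
        f0 = f_only(start)
        if not np.isfinite(f0):
            raise ValueError("fitness is non-finite at the start point")

    # tolerances pass through as configured; anything below double-precision
    # resolution just defers termination to the iteration cap
    scipy_method = _METHODS[cfg.method]
    tol = max(cfg.tolerance, 1e-20)
    if scipy_method == "trust-constr":
        options = {"maxiter": cfg.iterations, "gtol": tol, "xtol": tol, "verbose": 0}
    else:
        options = {"maxiter": cfg.iterations, "ftol": tol}

    hess = None
    if use_analytic and scipy_method == "trust-constr":
        # Gauss-Newton curvature: the fitness is a sum of squares, so the
        # residual-Jacobian outer product is the natural Hessian model and
        # lets the interior-point stage polish to near machine precision
        # within its iteration cap.
        def hess(v):
            _, _, H = fitness_and_grad(problem, v, n, spec, return_hessian=True)
            return H

    nit = 0
    try:
        if jac:
            res = minimize(fun, start, jac=True, method=scipy_method,
                           bounds=Bounds(lo, hi), hess=hess, options=options)
        else:
            res = minimize(fun, start, method=scipy_method,
                           bounds=Bounds(lo, hi),
                           jac=lambda v: numeric_gradient(fun, v, cfg.fd_step),
                           options=options)
        x = np.asarray(res.x, dtype=float)
        nit = int(getattr(res, "nit", 0) or 0)
    except _BudgetExceeded:
        x = best["x"] if best["x"] is not None else start

    x = np.clip(x, lo, hi)
    f1 = f_only(x)
    if not np.isfinite(f1) or f1 > f0:
        x, f1 = start, f0
    e = unpack(x, n)
    fv = FitnessValue(eps1(problem, e, spec), eps2(problem, e, spec.bc_weight))
    return RefineRun(x=x, fitness=fv, n_iterations=nit,
                     n_evaluations=counter["nfev"])
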