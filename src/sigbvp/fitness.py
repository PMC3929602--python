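"""Collocation fitness: mean-squared ODE residual plus boundary penalty.

For a trial expansion y the fitness is eps = eps1 + eps2 where

    eps1 = mean_i [ y''(x_i) + (a + m/x_i) y'(x_i) - f(x_i, y(x_i)) ]^2

over a collocation grid in [0, 1] and eps2 is half the sum of squared
Robin-row violations at the two endpoints.  The singular endpoint x = 0
is evaluated through the L'Hopital limit in
:func:`sigbvp.problems.ode_lhs_coefficient`.  Non-finite residuals (an
exploding exp(y) for a wild parameter vector) yield an infinite total so
optimizers simply discard such individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .basis import SigmoidExpansion, _phi_chain, unpack
from .problems import SingularBVP

__all__ = [
    "FitnessSpec",
    "FitnessValue",
    "ode_residual",
    "eps1",
    "eps2",
    "fitness",
    "fitness_population",
    "fitness_and_grad",
]

_SCHEMES = ("closed-equispaced-with-limit", "open-equispaced")


@dataclass(frozen=True)
class FitnessSpec:
    """Collocation grid, singularity policy, and boundary weight.

    The default grid is the 11 equispaced points i/10, i = 0..10, with the
    x = 0 singularity handled by the limit rule.  The open alternative
    i/11, i = 1..11 avoids the singular endpoint altogether.
    """

    grid: np.ndarray = field(default=None)
    grid_scheme: str = "closed-equispaced-with-limit"
    bc_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_scheme not in _SCHEMES:
            raise ValueError(f"grid_scheme must be one of {_SCHEMES}")
        grid = self.grid
        if grid is None:
            n = 11
            if self.grid_scheme == "closed-equispaced-with-limit":
                grid = np.linspace(0.0, 1.0, n)
            else:
                grid = np.arange(1, n + 1) / float(n)
        grid = np.asarray(grid, dtype=float).ravel()
        if grid.size == 0 or np.any(grid < 0.0) or np.any(grid > 1.0):
            raise ValueError("collocation points must lie in [0, 1]")
        if np.any(np.diff(grid) <= 0.0):
            raise ValueError("collocation grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        if not np.isfinite(self.bc_weight) or self.bc_weight < 0:
            raise ValueError("bc_weight must be a nonnegative real")

    @property
    def n_points(self) -> int:
        return self.grid.size

    @classmethod
    def from_scheme(cls, scheme: str = "closed-equispaced-with-limit", n_points: int = 11,
                    bc_weight: float = 1.0) -> "FitnessSpec":
        if n_points < 1:
            raise ValueError("n_points must be positive")
        if scheme == "closed-equispaced-with-limit":
            grid = np.linspace(0.0, 1.0, n_points)
        elif scheme == "open-equispaced":
            grid = np.arange(1, n_points + 1) / float(n_points)
        else:
            raise ValueError(f"grid_scheme must be one of {_SCHEMES}")
        return cls(grid=grid, grid_scheme=scheme, bc_weight=bc_weight)


@dataclass(frozen=True)
class FitnessValue:
    """The (eps1, eps2, total) triple; total is exactly eps1 + eps2."""

    eps1: float
    eps2: float

    @property
    def total(self) -> float:
        return self.eps1 + self.eps2


def _lhs_weights(problem: SingularBVP, x: np.ndarray):
    """Coefficients (w2, w1) so the ODE left side is w2*y'' + w1*y' pointwise.

    Interior: w2 = 1, w1 = a + m/x.  At x = 0 the limit rule folds the
    singular advection into the curvature term: w2 = 1 + m, w1 = a.
    """
    a, m = problem.a, problem.m
    with np.errstate(divide="ignore"):
        w1 = np.where(x > 0.0, a + m / np.where(x > 0.0, x, 1.0), a)
    w2 = np.where(x > 0.0, 1.0, 1.0 + m)
    return w2, w1


def ode_residual(problem: SingularBVP, e: SigmoidExpansion, x):
    """Pointwise collocation residual y'' + (a + m/x) y' - f(x, y)."""
    x = np.asarray(x, dtype=float)
    y, yp, ypp = e.all_values(x)
    w2, w1 = _lhs_weights(problem, x)
    with np.errstate(over="ignore", invalid="ignore"):
        r = w2 * ypp + w1 * yp - problem.rhs(x, y)
    return float(r) if r.ndim == 0 else r


def eps1(problem: SingularBVP, e: SigmoidExpansion, spec: FitnessSpec) -> float:
    """Mean squared ODE residual over the collocation grid."""
    r = ode_residual(problem, e, spec.grid)
    r = np.asarray(r)
    if not np.isfinite(r).all():
        return float("inf")
    return float(np.mean(r * r))


def eps2(problem: SingularBVP, e: SigmoidExpansion, bc_weight: float = 1.0) -> float:
    """Half the sum of squared Robin-row violations at the two endpoints."""
    total = 0.0
    for bc in (problem.bc_left, problem.bc_right):
        y, yp, _ = e.all_values(bc.location)
        total += bc.violation(y, yp) ** 2
    return float(bc_weight * 0.5 * total)


def fitness(problem: SingularBVP, e: SigmoidExpansion, spec: Optional[FitnessSpec] = None) -> FitnessValue:
    """The full fitness triple for one expansion."""
    spec = spec if spec is not None else FitnessSpec()
    return FitnessValue(eps1(problem, e, spec), eps2(problem, e, spec.bc_weight))


def fitness_population(problem: SingularBVP, V: np.ndarray, n: int,
                       spec: Optional[FitnessSpec] = None) -> np.ndarray:
    """Total fitness of every row of a (pop, 3n) parameter matrix at once.

    This is the hot path of the genetic algorithm; it evaluates the whole
    population on the grid plus both endpoints in a handful of einsums.
    Rows producing non-finite residuals get +inf.
    """
    spec = spec if spec is not None else FitnessSpec()
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = V[None, :]
    if V.shape[1] != 3 * n:
        raise ValueError(f"expected row length {3 * n}, got {V.shape[1]}")
    A, B, C = V[:, :n], V[:, n : 2 * n], V[:, 2 * n :]

    xg = spec.grid
    # evaluation points: grid plus the two boundary locations appended
    xs = np.concatenate([xg, [0.0, 1.0]])
    z = B[:, :, None] * xs[None, None, :] + C[:, :, None]  # (P, n, X)
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -700.0, 700.0)))
    s1 = s * (1.0 - s)
    s2 = s1 * (1.0 - 2.0 * s)
    ab = A * B
    y = np.einsum("pn,pnx->px", A, s)
    yp = np.einsum("pn,pnx->px", ab, s1)
    ypp = np.einsum("pn,pnx->px", ab * B, s2)

    G = xg.size
    w2, w1 = _lhs_weights(problem, xg)
    with np.errstate(over="ignore", invalid="ignore"):
        r = w2 * ypp[:, :G] + w1 * yp[:, :G] - problem.rhs(xg[None, :], y[:, :G])
        e1 = np.mean(r * r, axis=1)

    e2 = np.zeros(V.shape[0])
    for k, bc in ((G, problem.bc_left), (G + 1, problem.bc_right)):
        e2 += (bc.eta * y[:, k] + bc.xi * yp[:, k] - bc.gamma) ** 2
    e2 *= 0.5 * spec.bc_weight

    total = e1 + e2
    total[~np.isfinite(total)] = np.inf
    return total


def fitness_and_grad(problem: SingularBVP, v: np.ndarray, n: int,
                     spec: Optional[FitnessSpec] = None,
                     return_hessian: bool = False):
    """Total fitness and its exact gradient w.r.t. the 3n parameters.

    Differentiates the residual through the sigmoid chain (phi', phi'',
    phi''') and through df/dy; requires ``problem.rhs_dy``.  With
    ``return_hessian`` a Gauss-Newton Hessian approximation is appended.
    """
    if problem.rhs_dy is None:
        raise ValueError("analytic gradient needs problem.rhs_dy")
    spec = spec if spec is not None else FitnessSpec()
    v = np.asarray(v, dtype=float).ravel()
    e = unpack(v, n)
    a_, b_, c_ = e.alpha, e.b, e.c

    xs = np.concatenate([spec.grid, [0.0, 1.0]])
    z = np.multiply.outer(b_, xs) + c_[:, None]  # (n, X)
    s, s1, s2, s3 = _phi_chain(z)
    x_row = xs[None, :]
    ab = (a_ * b_)[:, None]
    ab2 = (a_ * b_ * b_)[:, None]
    y = a_ @ s
    yp = (a_ * b_) @ s1
    ypp = (a_ * b_ * b_) @ s2

    # partials of y, y', y'' w.r.t. alpha_i, b_i, c_i -> shape (n, X)
    dy_da, dy_db, dy_dc = s, a_[:, None] * s1 * x_row, a_[:, None] * s1
    dyp_da = b_[:, None] * s1
    dyp_db = a_[:, None] * (s1 + b_[:, None] * s2 * x_row)
    dyp_dc = ab * s2
    dypp_da = (b_ * b_)[:, None] * s2
    dypp_db = a_[:, None] * (2.0 * b_[:, None] * s2 + (b_ * b_)[:, None] * s3 * x_row)
    dypp_dc = ab2 * s3

    G = spec.grid.size
    w2, w1 = _lhs_weights(problem, spec.grid)
    with np.errstate(over="ignore", invalid="ignore"):
        f = problem.rhs(spec.grid, y[:G])
        fy = problem.rhs_dy(spec.grid, y[:G])
        r = w2 * ypp[:G] + w1 * yp[:G] - f
    if not np.isfinite(r).all():
        bad = (float("inf"), np.full(3 * n, np.nan))
        return bad + (np.eye(3 * n),) if return_hessian else bad

    def _dr(dy, dyp, dypp):
        return w2 * dypp[:, :G] + w1 * dyp[:, :G] - fy * dy[:, :G]

    coef = 2.0 * r / G  # d eps1 / d r
    g1 = np.concatenate([
        _dr(dy_da, dyp_da, dypp_da) @ coef,
        _dr(dy_db, dyp_db, dypp_db) @ coef,
        _dr(dy_dc, dyp_dc, dypp_dc) @ coef,
    ])
    e1 = float(np.mean(r * r))

    e2 = 0.0
    g2 = np.zeros(3 * n)
    for k, bc in ((G, problem.bc_left), (G + 1, problem.bc_right)):
        viol = bc.eta * y[k] + bc.xi * yp[k] - bc.gamma
        e2 += 0.5 * viol**2
        dviol = np.concatenate([
            bc.eta * dy_da[:, k] + bc.xi * dyp_da[:, k],
            bc.eta * dy_db[:, k] + bc.xi * dyp_db[:, k],
            bc.eta * dy_dc[:, k] + bc.xi * dyp_dc[:, k],
        ])
        g2 += viol * dviol
    e2 *= spec.bc_weight
    g2 *= spec.bc_weight

    if not return_hessian:
        return e1 + e2, g1 + g2

    # Gauss-Newton curvature: eps1 and eps2 are sums of squares, so
    # J^T J (residual Jacobian outer products) approximates the Hessian,
    # exactly at a zero-residual minimum.
    Jr = np.vstack([
        _dr(dy_da, dyp_da, dypp_da),
        _dr(dy_db, dyp_db, dypp_db),
        _dr(dy_dc, dyp_dc, dypp_dc),
    ])  # (3n, G)
    H = (2.0 / G) * (Jr @ Jr.T)
    for k, bc in ((G, problem.bc_left), (G + 1, problem.bc_right)):
        dviol = np.concatenate([
            bc.eta * dy_da[:, k] + bc.xi * dyp_da[:, k],
            bc.eta * dy_db[:, k] + bc.xi * dyp_db[:, k],
            bc.eta * dy_dc[:, k] + bc.xi * dyp_dc[:, k],
        ])
        H += spec.bc_weight * np.outer(dviol, dviol)
    return e1 + e2, g1 + g2, H
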