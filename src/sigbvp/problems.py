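"""Singular two-point boundary-value problems on [0, 1].

The problem class is

    y''(x) + (a + m/x) y'(x) = f(x, y),   0 <= x <= 1,

with Robin conditions ``eta*y + xi*y'`` fixed at each endpoint.  The
coefficient ``m/x`` is unbounded at the left endpoint; the classical
physiological cases are a = 0 with m = 0, 1, 2 (tumour growth, thermal
explosion in a cylinder, oxygen diffusion in a spherical cell with
Michaelis-Menten uptake, heat distribution in the human head).

Three benchmark problems with closed-form solutions are bundled
(:func:`make_example1` through :func:`make_example3`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "RobinCondition",
    "SingularBVP",
    "make_example1",
    "make_example2",
    "make_example3",
    "get_problem",
    "ode_lhs_coefficient",
]


@dataclass(frozen=True)
class RobinCondition:
    """Boundary row ``eta * y(loc) + xi * y'(loc) = gamma`` at ``location``."""

    eta: float
    xi: float
    gamma: float
    location: float  # 0.0 or 1.0

    def __post_init__(self) -> None:
        if self.eta == 0.0 and self.xi == 0.0:
            raise ValueError("Robin condition needs (eta, xi) != (0, 0)")
        if self.location not in (0.0, 1.0):
            raise ValueError("boundary location must be 0 or 1")

    def violation(self, y: float, yprime: float) -> float:
        """Signed residual of the boundary row for given y, y' at ``location``."""
        return self.eta * y + self.xi * yprime - self.gamma


@dataclass(frozen=True)
class SingularBVP:
    """One singular BVP instance, optionally with its closed-form solution.

    ``rhs(x, y)`` must accept numpy arrays and broadcast.  ``rhs_dy`` is
    df/dy, used for analytic gradients of the collocation fitness; when
    absent the refiners fall back to finite differences.  ``exact``,
    ``exact_dy`` and ``exact_d2y`` (solution and its first two derivatives)
    make error reports and residual checks free of numerical
    differentiation.
    """

    a: float
    m: float
    rhs: Callable
    bc_left: RobinCondition
    bc_right: RobinCondition
    rhs_dy: Optional[Callable] = None
    exact: Optional[Callable] = None
    exact_dy: Optional[Callable] = None
    exact_d2y: Optional[Callable] = None
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.bc_left.location != 0.0 or self.bc_right.location != 1.0:
            raise ValueError("bc_left must sit at x=0 and bc_right at x=1")

    @property
    def has_exact(self) -> bool:
        return self.exact is not None


def ode_lhs_coefficient(problem: SingularBVP, x, yprime, y2prime=0.0):
    """Advection term ``(a + m/x) * y'`` with the singular limit at x = 0.

    At the singular endpoint the term ``m*y'/x`` is replaced by its limit
    ``m*y''(0)`` (valid whenever y'(0) = 0, which every bundled problem's
    solution satisfies), so collocation grids may include x = 0.
    """
    x = np.asarray(x, dtype=float)
    yprime = np.asarray(yprime, dtype=float)
    y2prime = np.asarray(y2prime, dtype=float)
    a, m = problem.a, problem.m
    with np.errstate(divide="ignore", invalid="ignore"):
        interior = (a + m / x) * yprime
    at_zero = a * yprime + m * y2prime
    out = np.where(x > 0.0, interior, at_zero)
    return out if out.ndim else float(out)


def make_example1() -> SingularBVP:
    """Thermal-explosion benchmark: y'' + y'/x = -exp(y), y'(0)=0, y(1)=0.

    Closed form: y(x) = 2*ln((c+1)/(c*x**2+1)) with c = 3 - 2*sqrt(2).
    """
    c = 3.0 - 2.0 * np.sqrt(2.0)

    def rhs(x, y):
        return -np.exp(y)

    def rhs_dy(x, y):
        return -np.exp(y)

    def exact(x):
        x = np.asarray(x, dtype=float)
        return 2.0 * np.log((c + 1.0) / (c * x**2 + 1.0))

    def exact_dy(x):
        x = np.asarray(x, dtype=float)
        return -4.0 * c * x / (c * x**2 + 1.0)

    def exact_d2y(x):
        x = np.asarray(x, dtype=float)
        return 4.0 * c * (c * x**2 - 1.0) / (c * x**2 + 1.0) ** 2

    return SingularBVP(
        a=0.0,
        m=1.0,
        rhs=rhs,
        rhs_dy=rhs_dy,
        bc_left=RobinCondition(0.0, 1.0, 0.0, 0.0),
        bc_right=RobinCondition(1.0, 0.0, 0.0, 1.0),
        exact=exact,
        exact_dy=exact_dy,
        exact_d2y=exact_d2y,
        label="example1",
    )


def _example23_core(m: float):
    """Shared ODE pieces of the two Michaelis-Menten-type benchmarks."""
    if m <= 0:
        raise ValueError(f"singular coefficient m must be positive, got {m}")

    def rhs(x, y):
        x = np.asarray(x, dtype=float)
        return 5.0 * x**3 * (5.0 * x**5 * np.exp(y) - x - m - 4.0) / (4.0 + x**5)

    def rhs_dy(x, y):
        x = np.asarray(x, dtype=float)
        return 25.0 * x**8 * np.exp(y) / (4.0 + x**5)

    def exact(x):
        x = np.asarray(x, dtype=float)
        return -np.log(4.0 + x**5)

    def exact_dy(x):
        x = np.asarray(x, dtype=float)
        return -5.0 * x**4 / (4.0 + x**5)

    def exact_d2y(x):
        x = np.asarray(x, dtype=float)
        return (5.0 * x**8 - 80.0 * x**3) / (4.0 + x**5) ** 2

    return rhs, rhs_dy, exact, exact_dy, exact_d2y


# Right boundary row shared by examples 2 and 3: y(1) + 5 y'(1) = ln(1/5) - 5.
_BC_RIGHT_23 = RobinCondition(1.0, 5.0, np.log(1.0 / 5.0) - 5.0, 1.0)


def make_example2(m: float) -> SingularBVP:
    """y'' + (1 + m/x) y' = 5x^3(5x^5 e^y - x - m - 4)/(4 + x^5) with Neumann left BC.

    Boundary rows: y'(0) = 0 and y(1) + 5 y'(1) = ln(1/5) - 5.  Closed form
    y(x) = -ln(4 + x^5) for every m > 0.
    """
    rhs, rhs_dy, exact, exact_dy, exact_d2y = _example23_core(m)
    return SingularBVP(
        a=1.0,
        m=float(m),
        rhs=rhs,
        rhs_dy=rhs_dy,
        bc_left=RobinCondition(0.0, 1.0, 0.0, 0.0),
        bc_right=_BC_RIGHT_23,
        exact=exact,
        exact_dy=exact_dy,
        exact_d2y=exact_d2y,
        label=f"example2(m={m:g})",
    )


def make_example3(m: float) -> SingularBVP:
    """Same ODE as :func:`make_example2` with a Dirichlet left boundary.

    Boundary rows: y(0) = ln(1/4) and y(1) + 5 y'(1) = ln(1/5) - 5.
    """
    rhs, rhs_dy, exact, exact_dy, exact_d2y = _example23_core(m)
    return SingularBVP(
        a=1.0,
        m=float(m),
        rhs=rhs,
        rhs_dy=rhs_dy,
        bc_left=RobinCondition(1.0, 0.0, np.log(1.0 / 4.0), 0.0),
        bc_right=_BC_RIGHT_23,
        exact=exact,
        exact_dy=exact_dy,
        exact_d2y=exact_d2y,
        label=f"example3(m={m:g})",
    )


def get_problem(name: str, m: Optional[float] = None) -> SingularBVP:
    """Look a bundled benchmark up by name ("example1"/"example2"/"example3")."""
    key = name.strip().lower()
    if key == "example1":
        return make_example1()
    if key == "example2":
        if m is None:
            raise ValueError("example2 requires the singular coefficient m")
        return make_example2(m)
    if key == "example3":
        if m is None:
            raise ValueError("example3 requires the singular coefficient m")
        return make_example3(m)
    raise ValueError(f"unknown problem {name!r}")
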