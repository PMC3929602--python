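"""Log-sigmoid basis expansion of the trial solution.

The trial solution is y(x) = sum_i alpha_i * phi(b_i*x + c_i) with
phi(z) = 1/(1 + exp(-z)).  Because phi' = phi*(1-phi) and
phi'' = phi*(1-phi)*(1-2*phi), the first and second derivatives of the
trial solution are available in closed form, which is what makes the
collocation residual cheap and exactly differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["logsigmoid", "SigmoidExpansion", "pack", "unpack"]


def logsigmoid(x):
    """Stable logistic sigmoid 1/(1 + exp(-x)); saturates instead of overflowing."""
    return expit(np.asarray(x, dtype=float))


def _phi_chain(z):
    """phi and its first three derivatives at z, via the algebraic identities."""
    s = expit(z)
    s1 = s * (1.0 - s)
    s2 = s1 * (1.0 - 2.0 * s)
    s3 = s1 * (1.0 - 6.0 * s + 6.0 * s * s)
    return s, s1, s2, s3


@dataclass(frozen=True)
class SigmoidExpansion:
    """n-term log-sigmoid expansion with amplitudes alpha, weights b, biases c."""

    alpha: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alpha", "b", "c"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (self.alpha.shape == self.b.shape == self.c.shape) or self.alpha.ndim != 1:
            raise ValueError("alpha, b, c must be 1-D arrays of a common length")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.b).all() and np.isfinite(self.c).all()):
            raise ValueError("expansion parameters must be finite")

    @property
    def n(self) -> int:
        return self.alpha.size

    def _z(self, x):
        x = np.asarray(x, dtype=float)
        return np.multiply.outer(x, self.b) + self.c  # (..., n)

    def value(self, x):
        """y(x) = sum_i alpha_i phi(b_i x + c_i)."""
        out = expit(self._z(x)) @ self.alpha
        return float(out) if out.ndim == 0 else out

    def dvalue(self, x):
        """y'(x) = sum_i alpha_i b_i phi'(b_i x + c_i)."""
        s = expit(self._z(x))
        out = (s * (1.0 - s)) @ (self.alpha * self.b)
        return float(out) if out.ndim == 0 else out

    def d2value(self, x):
        """y''(x) = sum_i alpha_i b_i^2 phi''(b_i x + c_i)."""
        s = expit(self._z(x))
        out = (s * (1.0 - s) * (1.0 - 2.0 * s)) @ (self.alpha * self.b**2)
        return float(out) if out.ndim == 0 else out

    def all_values(self, x):
        """(y, y', y'') at x in one sigmoid evaluation."""
        s = expit(self._z(x))
        s1 = s * (1.0 - s)
        s2 = s1 * (1.0 - 2.0 * s)
        ab = self.alpha * self.b
        return s @ self.alpha, s1 @ ab, s2 @ (ab * self.b)


def pack(e: SigmoidExpansion) -> np.ndarray:
    """Flatten an expansion to the chromosome layout [alpha_1..n, b_1..n, c_1..n]."""
    return np.concatenate([e.alpha, e.b, e.c])


def unpack(v, n: int) -> SigmoidExpansion:
    """Inverse of :func:`pack`; rejects vectors whose length is not 3n."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size != 3 * n:
        raise ValueError(f"parameter vector of length {v.size} does not match 3*n = {3 * n}")
    return SigmoidExpansion(v[:n], v[n : 2 * n], v[2 * n :])
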