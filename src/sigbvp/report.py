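"""Solve results and error reports.

A :class:`SolveResult` is the results object returned by the driver and by
:meth:`sigbvp.model.SigmoidCollocationModel.fit`: the optimal parameter
vector, its fitness triple, the best-fitness trace, and enough metadata to
reproduce the run.  :func:`error_report` compares a trial expansion with a
problem's closed-form solution on a reporting grid (default 0, 0.1, ..., 1),
using the signed convention error = exact - approx.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .basis import SigmoidExpansion, unpack
from .fitness import FitnessSpec, FitnessValue
from .problems import SingularBVP

__all__ = ["SolveResult", "ErrorReport", "error_report", "write_report", "read_report"]

DEFAULT_REPORT_GRID = np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass(frozen=True)
class ErrorReport:
    """Per-point solution table with signed errors (exact - approx)."""

    grid: np.ndarray
    approx: np.ndarray
    exact: Optional[np.ndarray]
    signed_error: Optional[np.ndarray]

    @property
    def max_abs_error(self) -> Optional[float]:
        if self.signed_error is None:
            return None
        return float(np.max(np.abs(self.signed_error)))

    def to_frame(self) -> pd.DataFrame:
        data = {"x": self.grid}
        if self.exact is not None:
            data["exact"] = self.exact
        data["approx"] = self.approx
        if self.signed_error is not None:
            data["signed_error"] = self.signed_error
        return pd.DataFrame(data)


def error_report(problem: SingularBVP, e: SigmoidExpansion,
                 eval_grid: Optional[np.ndarray] = None) -> ErrorReport:
    """Tabulate approx vs exact on the reporting grid.

    Problems without a closed-form solution get a table without the error
    columns.
    """
    grid = np.asarray(eval_grid, dtype=float) if eval_grid is not None else DEFAULT_REPORT_GRID
    approx = np.atleast_1d(e.value(grid))
    if problem.exact is None:
        return ErrorReport(grid=grid, approx=approx, exact=None, signed_error=None)
    exact = np.atleast_1d(problem.exact(grid))
    return ErrorReport(grid=grid, approx=approx, exact=exact, signed_error=exact - approx)


@dataclass
class SolveResult:
    """Best parameters and diagnostics of one solve.

    ``trace`` is the optimizer's best-total-fitness history, non-increasing
    by construction (elitism in the GA stage, the no-worsening contract in
    the refinement stage).
    """

    best_params: np.ndarray
    best_fitness: FitnessValue
    trace: List[Tuple[int, float]]
    method: str
    seed: int
    restarts: int = 1
    problem: Optional[SingularBVP] = None
    spec: Optional[FitnessSpec] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_basis(self) -> int:
        return self.best_params.size // 3

    @property
    def expansion(self) -> SigmoidExpansion:
        return unpack(self.best_params, self.n_basis)

    def predict(self, x):
        """Evaluate the fitted trial solution at x."""
        return self.expansion.value(x)

    def error_report(self, eval_grid: Optional[np.ndarray] = None) -> ErrorReport:
        if self.problem is None:
            raise ValueError("result carries no problem; call error_report() directly")
        return error_report(self.problem, self.expansion, eval_grid)

    def config_hash(self) -> str:
        blob = json.dumps(
            {"method": self.method, "seed": self.seed, "restarts": self.restarts,
             "n_basis": self.n_basis, **{k: repr(v) for k, v in sorted(self.meta.items())}},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def summary(self) -> str:
        """Human-readable run summary with the solution table."""
        lines = [
            "Sigmoid-collocation solve",
            "=" * 60,
            f"problem:   {self.problem.label if self.problem is not None else '?'}",
            f"method:    {self.method}    seed: {self.seed}    restarts: {self.restarts}",
            f"n_basis:   {self.n_basis}",
            f"fitness:   eps1={self.best_fitness.eps1:.6e}  eps2={self.best_fitness.eps2:.6e}"
            f"  total={self.best_fitness.total:.6e}",
            f"config:    {self.config_hash()}",
        ]
        if self.problem is not None:
            rep = self.error_report()
            lines.append("-" * 60)
            lines.append(rep.to_frame().to_string(index=False, float_format=lambda v: f"{v: .10f}"))
            if rep.max_abs_error is not None:
                lines.append(f"max |exact - approx| = {rep.max_abs_error:.6e}")
        return "\n".join(lines)


def write_report(report: ErrorReport, result: Optional[SolveResult], path,
                 format: str = "csv") -> Path:
    """Write the solution table plus run metadata; returns the path written.

    CSV keeps the table at full double precision (metadata goes to a
    sibling ``<path>.meta.json``); JSON bundles table, metadata and the
    full parameter vector at 17 significant digits in one file.
    """
    path = Path(path)
    frame = report.to_frame()
    meta = {}
    if result is not None:
        meta = {
            "method": result.method,
            "seed": result.seed,
            "restarts": result.restarts,
            "config_hash": result.config_hash(),
            "fitness": {"eps1": result.best_fitness.eps1,
                        "eps2": result.best_fitness.eps2,
                        "total": result.best_fitness.total},
            "best_params": [float(f"{v:.17g}") for v in result.best_params],
        }
    try:
        if format == "csv":
            frame.to_csv(path, index=False, float_format="%.17g")
            if meta:
                Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
        elif format == "json":
            payload = {"table": {k: frame[k].tolist() for k in frame.columns}, "meta": meta}
            if report.max_abs_error is not None:
                payload["max_abs_error"] = report.max_abs_error
            path.write_text(json.dumps(payload, indent=2))
        else:
            raise ValueError(f"unknown report format {format!r}")
    except OSError as exc:
        raise OSError(f"could not write report to {path}: {exc}") from exc
    return path


def read_report(path, format: str = "csv") -> pd.DataFrame:
    """Round-trip reader for :func:`write_report` tables."""
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["table"])
    raise ValueError(f"unknown report format {format!r}")
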