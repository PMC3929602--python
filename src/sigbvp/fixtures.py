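"""Bundled reference parameter sets for the benchmark problems.

Each fixture is a 10-triple (alpha, b, c) table transcribed from the
benchmark study's reported optima; plugging one into the log-sigmoid
expansion reconstructs the corresponding reference solution column without
running any optimization.  Names follow ``<problem>[-m<value>]-<method>``,
e.g. ``example1-ga-ipa`` or ``example3-m0.25-ga-asa``.

One caveat: the ``example3-m0.25-ga-ipa`` block is corrupted in its source
(see the file header) and does not reproduce its reference column; it is
kept as transcribed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .basis import SigmoidExpansion

__all__ = ["list_fixtures", "load_fixture", "fixture_problem_args"]

_N_BASIS = 10


def _normalize(name: str) -> str:
    return name.strip().lower().replace("-", "_")


def list_fixtures() -> list[str]:
    """Fixture names, in the canonical dashed form."""
    files = resources.files("sigbvp") / "tables"
    names = sorted(p.name[: -len(".tsv")] for p in files.iterdir() if p.name.endswith(".tsv"))
    return [n.replace("_", "-") for n in names]


def load_fixture(name: str) -> SigmoidExpansion:
    """Load a reference parameter set as a :class:`SigmoidExpansion`."""
    fname = _normalize(name) + ".tsv"
    ref = resources.files("sigbvp") / "tables" / fname
    if not ref.is_file():
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}")
    rows = []
    with ref.open("r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("alpha"):
                continue
            rows.append([float(tok) for tok in line.split()])
    arr = np.asarray(rows, dtype=float)
    if arr.size != 3 * _N_BASIS:
        raise ValueError(f"fixture {name!r} holds {arr.size} parameters, expected {3 * _N_BASIS}")
    return SigmoidExpansion(arr[:, 0], arr[:, 1], arr[:, 2])


def fixture_problem_args(name: str) -> tuple[str, float | None]:
    """(problem name, m) that a fixture belongs to, parsed from its name."""
    parts = _normalize(name).split("_")
    problem = parts[0]
    m = None
    for tok in parts[1:]:
        if tok.startswith("m") and tok[1:].replace(".", "", 1).isdigit():
            m = float(tok[1:])
    return problem, m
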