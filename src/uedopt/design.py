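"""U-type uniform design tables and L2-discrepancy measures.

A uniform design U_n(q^s) spreads n experimental runs over s factor
columns so that the runs fill the factor space as evenly as possible.
In the U-type form used here the number of levels q equals the number
of runs n, i.e. every column is a permutation of 1..n.  Uniformity is
scored by the squared centered L2-discrepancy (CD2) and the squared
wrap-around L2-discrepancy (WD2) of the design's midpoint-normalized
point set in the unit hypercube: smaller values mean a more uniform
design.

The module ships the classic 17-run, 8-column table used for mixed
2/3-level factor studies (`builtin_u17_8`), and constructs new tables
with the good-lattice-point (GLP) rule followed by a seeded level-swap
descent that minimizes CD2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InfeasibleDesignError, InvalidDesignError

__all__ = [
    "UniformDesignTable",
    "DiscrepancyResult",
    "builtin_u17_8",
    "normalize_midpoints",
    "cd2",
    "wd2",
    "discrepancy",
    "construct_glp_design",
    "read_design_csv",
    "write_design_csv",
]


@dataclass(frozen=True)
class UniformDesignTable:
    """An n x s U-type design: every column is a permutation of 1..n.

    Parameters
    ----------
    entries : array-like of int, shape (n_runs, n_cols)
        Levels in 1..n_runs.
    label : str
        Free-text identifier, e.g. ``"U17(17^8)"``.
    """

    entries: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries)
        if arr.ndim != 2:
            raise InvalidDesignError("design entries must be a 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise InvalidDesignError("design entries must be integers")
            arr = arr.astype(np.int64)
        arr = np.ascontiguousarray(arr, dtype=np.int64)
        n, s = arr.shape
        if n < 2 or s < 1:
            raise InvalidDesignError(f"need n_runs >= 2 and n_cols >= 1, got {n}x{s}")
        expected = np.arange(1, n + 1)
        for j in range(s):
            if not np.array_equal(np.sort(arr[:, j]), expected):
                raise InvalidDesignError(
                    f"column {j + 1} is not a permutation of 1..{n}"
                )
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)

    @property
    def n_runs(self) -> int:
        return self.entries.shape[0]

    @property
    def n_cols(self) -> int:
        return self.entries.shape[1]

    def column(self, j: int) -> np.ndarray:
        """Return design column ``j`` (0-based) as a 1-D array."""
        return self.entries[:, j].copy()


@dataclass(frozen=True)
class DiscrepancyResult:
    """Squared centered (cd2) and wrap-around (wd2) L2-discrepancies."""

    cd2: float
    wd2: float

    def __post_init__(self) -> None:
        if self.cd2 < 0 or self.wd2 < 0:
            raise ValueError("squared discrepancies must be nonnegative")


def builtin_u17_8() -> UniformDesignTable:
    """The packaged 17-run, 8-column U-type uniform design table."""
    path = resources.files("uedopt.data").joinpath("table5_u17_8.csv")
    with resources.as_file(path) as p:
        return read_design_csv(p, label="U17(17^8)")


def normalize_midpoints(design: UniformDesignTable) -> np.ndarray:
    """Map levels to midpoints of equal cells in (0,1): x = (u - 0.5)/q.

    Level 1 of a q-level column maps to 0.5/q, level q to (q-0.5)/q, and
    (for odd q) the middle level to exactly 0.5.  The mapping is strictly
    increasing in the level, so level order is preserved.
    """
    q = design.n_runs
    u = design.entries
    if u.min() < 1 or u.max() > q:
        raise InvalidDesignError("levels outside 1..q")
    return (u - 0.5) / q


def _cd2_points(x: np.ndarray) -> float:
    # Vectorized Hickernell centered L2-discrepancy (squared) of points in (0,1)^s.
    n, s = x.shape
    a = np.abs(x - 0.5)
    one_sum = np.prod(1.0 + 0.5 * a - 0.5 * a**2, axis=1).sum()
    d = np.abs(x[:, None, :] - x[None, :, :])
    cross = np.prod(1.0 + 0.5 * a[:, None, :] + 0.5 * a[None, :, :] - 0.5 * d, axis=2)
    return (13.0 / 12.0) ** s - (2.0 / n) * one_sum + cross.sum() / n**2


def _wd2_points(x: np.ndarray) -> float:
    # Vectorized squared wrap-around L2-discrepancy; |x-y|(1-|x-y|) is the
    # periodic distance kernel, so the value is invariant to cyclic shifts.
    n, s = x.shape
    d = np.abs(x[:, None, :] - x[None, :, :])
    cross = np.prod(1.5 - d * (1.0 - d), axis=2)
    return -((4.0 / 3.0) ** s) + cross.sum() / n**2


def cd2(design: UniformDesignTable) -> float:
    """Squared centered L2-discrepancy of the midpoint-normalized design."""
    return float(_cd2_points(normalize_midpoints(design)))


def wd2(design: UniformDesignTable) -> float:
    """Squared wrap-around L2-discrepancy of the midpoint-normalized design."""
    return float(_wd2_points(normalize_midpoints(design)))


def discrepancy(design: UniformDesignTable) -> DiscrepancyResult:
    """Both squared discrepancies of a design in one call."""
    return DiscrepancyResult(cd2=cd2(design), wd2=wd2(design))


def _coprime_generators(n: int) -> list[int]:
    return [h for h in range(1, n) if math.gcd(h, n) == 1]


def _glp_table(n: int, generators: tuple[int, ...]) -> np.ndarray:
    i = np.arange(1, n + 1)[:, None]
    h = np.asarray(generators)[None, :]
    return ((i * h - 1) % n) + 1


def _swap_descent(entries: np.ndarray, q: int) -> tuple[np.ndarray, float]:
    """Steepest-descent pairwise level swaps within columns, to a local CD2 min."""
    t = entries.copy()
    n, s = t.shape
    best = _cd2_points((t - 0.5) / q)
    improved = True
    while improved:
        improved = False
        move = None
        for j in range(s):
            col = t[:, j]
            for i1 in range(n - 1):
                for i2 in range(i1 + 1, n):
                    col[i1], col[i2] = col[i2], col[i1]
                    v = _cd2_points((t - 0.5) / q)
                    col[i1], col[i2] = col[i2], col[i1]
                    if v < best - 1e-15:
                        best, move, improved = v, (j, i1, i2), True
        if move is not None:
            j, i1, i2 = move
            t[i1, j], t[i2, j] = t[i2, j], t[i1, j]
    return t, best


def construct_glp_design(
    n_runs: int,
    n_cols: int,
    search_budget: int = 2000,
    seed: int = 0,
    *,
    refine_restarts: int = 16,
) -> UniformDesignTable:
    """Construct a U-type design minimizing the centered L2-discrepancy.

    Candidate tables come from the good-lattice-point rule
    ``u_ij = ((i * h_j - 1) mod n) + 1`` over generator subsets h coprime
    to n.  All subsets are scanned when their count fits in
    ``search_budget``; otherwise a seeded random subset search of
    ``search_budget`` draws is used.  The best lattice table is then
    refined by steepest-descent level swaps within columns, with
    ``refine_restarts`` additional seeded random restarts, keeping the
    overall CD2 minimizer.  Ties prefer the lexicographically smallest
    generator tuple.

    Raises
    ------
    InfeasibleDesignError
        If ``n_cols`` is not smaller than both ``n_runs`` and the number
        of generators coprime to ``n_runs``.
    """
    if n_runs < 3:
        raise InfeasibleDesignError("need n_runs >= 3")
    if n_cols < 1 or n_cols >= n_runs:
        raise InfeasibleDesignError("need 1 <= n_cols < n_runs")
    gens = _coprime_generators(n_runs)
    if n_cols > len(gens):
        raise InfeasibleDesignError(
            f"only {len(gens)} coprime generators available for n={n_runs}, "
            f"cannot fill {n_cols} columns"
        )
    q = n_runs
    rng = np.random.default_rng(seed)

    n_subsets = math.comb(len(gens), n_cols)
    best_val = math.inf
    best_gens: tuple[int, ...] | None = None
    if n_subsets <= search_budget:
        candidates = itertools.combinations(gens, n_cols)
    else:
        seen: set[tuple[int, ...]] = set()
        draws = []
        for _ in range(search_budget):
            sub = tuple(sorted(rng.choice(gens, size=n_cols, replace=False).tolist()))
            if sub not in seen:
                seen.add(sub)
                draws.append(sub)
        candidates = iter(sorted(draws))
    for sub in candidates:
        v = _cd2_points((_glp_table(q, tuple(sub)) - 0.5) / q)
        if v < best_val - 1e-15:  # strict improvement: keeps lexicographic ties
            best_val, best_gens = v, tuple(sub)
    assert best_gens is not None

    # Swap-descent refinement: once from the lattice start, then from
    # seeded random U-type starts; basins are small, restarts escape them.
    start = _glp_table(q, best_gens)
    best_t, best_v = _swap_descent(start, q)
    for _ in range(refine_restarts):
        t0 = np.column_stack([rng.permutation(q) + 1 for _ in range(n_cols)])
        t, v = _swap_descent(t0, q)
        if v < best_v - 1e-15:
            best_t, best_v = t, v
    label = f"U{n_runs}({n_runs}^{n_cols})"
    return UniformDesignTable(entries=best_t, label=label)


def write_design_csv(design: UniformDesignTable, path: str | Path) -> None:
    """Write ``run,c1,...,cs`` CSV with integer levels."""
    df = pd.DataFrame(
        design.entries,
        columns=[f"c{j + 1}" for j in range(design.n_cols)],
    )
    df.insert(0, "run", np.arange(1, design.n_runs + 1))
    df.to_csv(path, index=False)


def read_design_csv(path: str | Path, label: str = "") -> UniformDesignTable:
    """Read a design written by :func:`write_design_csv` (round-trips exactly)."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "run"]
    return UniformDesignTable(entries=df[cols].to_numpy(dtype=np.int64), label=label)
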