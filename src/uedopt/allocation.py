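"""Mixed-level factor allocation onto U-type design columns.

A q-level U-type column carries more levels than a real 2- or 3-level
factor, so each column is collapsed to the factor's level count by the
pseudo-level rule ``ceil(u * q' / q)``, which keeps the level
frequencies balanced within one run.  The collapsed pseudo-level then
indexes the factor's actual value list, giving the runnable experiment
plan.

The default factor set is the two-convolution-layer study: kernel
size, filter count, stride and padding for each of conv1 and conv2
(four 3-level and four 2-level factors).  The plan actually run in
that study is shipped verbatim as `builtin_plan_table6`, because the
published plan is the anchor for its published responses and is not
reproducible from the published design table by any monotone
collapsing of its printed columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import UniformDesignTable
from .exceptions import InfeasibleDesignError, ValidationError

__all__ = [
    "FactorSpec",
    "ExperimentPlan",
    "default_factors",
    "collapse_levels",
    "allocate",
    "builtin_plan_table6",
    "read_plan_csv",
    "write_plan_csv",
]


@dataclass(frozen=True)
class FactorSpec:
    """A named discrete factor with 2 or 3 strictly increasing level values."""

    name: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        if not 2 <= len(levels) <= 3:
            raise ValidationError(f"factor {self.name!r}: need 2 or 3 levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValidationError(f"factor {self.name!r}: levels must strictly increase")
        object.__setattr__(self, "levels", levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ExperimentPlan:
    """Factor settings to run: an n_runs x n_factors matrix of level values."""

    factors: tuple[FactorSpec, ...]
    settings: np.ndarray
    run_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        factors = tuple(self.factors)
        arr = np.ascontiguousarray(np.asarray(self.settings, dtype=float))
        if arr.ndim != 2 or arr.shape[1] != len(factors):
            raise ValidationError("settings must be n_runs x n_factors")
        for j, f in enumerate(factors):
            if not np.isin(arr[:, j], f.levels).all():
                raise ValidationError(
                    f"settings column for factor {f.name!r} contains non-level values"
                )
        run_ids = tuple(self.run_ids) or tuple(range(1, arr.shape[0] + 1))
        if len(run_ids) != arr.shape[0]:
            raise ValidationError("run_ids length must match settings rows")
        arr.setflags(write=False)
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "settings", arr)
        object.__setattr__(self, "run_ids", run_ids)

    @property
    def n_runs(self) -> int:
        return self.settings.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.settings, columns=list(self.factor_names))
        df.insert(0, "run", list(self.run_ids))
        return df


def default_factors() -> tuple[FactorSpec, ...]:
    """The eight conv1/conv2 hyperparameter factors of the default study."""
    path = resources.files("uedopt.data").joinpath("table3_factors.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    out = []
    for _, row in df.iterrows():
        levels = [row[c] for c in ("level1", "level2", "level3") if pd.notna(row[c])]
        out.append(FactorSpec(name=str(row["name"]), levels=tuple(levels)))
    return tuple(out)


def collapse_levels(
    column: Sequence[int], q_prime: int, q: int | None = None
) -> np.ndarray:
    """Collapse a q-level column to q' pseudo-levels by ``ceil(u * q' / q)``.

    For a column that is a permutation of 1..q the resulting pseudo-level
    counts differ by at most one, so the collapsed factor stays balanced.
    """
    col = np.asarray(column, dtype=np.int64)
    if q is None:
        q = len(col)
    if q_prime not in (2, 3):
        raise ValidationError("q_prime must be 2 or 3")
    if q_prime > q:
        raise ValidationError("q_prime cannot exceed q")
    if col.min(initial=q) < 1 or col.max(initial=1) > q:
        raise ValidationError(f"column entries must lie in 1..{q}")
    return -(-(col * q_prime) // q)  # ceil division


def allocate(
    design: UniformDesignTable, factors: Sequence[FactorSpec]
) -> ExperimentPlan:
    """Map design columns onto factors: column j (collapsed) feeds factor j."""
    factors = tuple(factors)
    if design.n_cols < len(factors):
        raise InfeasibleDesignError(
            f"design has {design.n_cols} columns but {len(factors)} factors requested"
        )
    n = design.n_runs
    settings = np.empty((n, len(factors)))
    for j, f in enumerate(factors):
        pseudo = collapse_levels(design.column(j), f.n_levels, q=n)
        settings[:, j] = np.asarray(f.levels)[pseudo - 1]
    return ExperimentPlan(factors=factors, settings=settings)


def builtin_plan_table6() -> ExperimentPlan:
    """The 17-run plan actually executed in the default study, verbatim."""
    path = resources.files("uedopt.data").joinpath("table6_plan.csv")
    with resources.as_file(path) as p:
        return read_plan_csv(p, factors=default_factors())


def write_plan_csv(plan: ExperimentPlan, path: str | Path) -> None:
    """Write ``run,<factor names...>`` CSV, factor names quoted."""
    df = plan.to_dataframe()
    # integers print without a trailing .0 so the file matches the plan layout
    for c in df.columns:
        if (df[c] == df[c].astype(np.int64)).all():
            df[c] = df[c].astype(np.int64)
    import csv

    df.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC)


def read_plan_csv(
    path: str | Path, factors: Sequence[FactorSpec] | None = None
) -> ExperimentPlan:
    """Read a plan CSV; factor specs are inferred from observed values if omitted."""
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "run"]
    if factors is None:
        factors = tuple(
            FactorSpec(name=c, levels=tuple(sorted(df[c].unique()))) for c in names
        )
    else:
        factors = tuple(factors)
        if [f.name for f in factors] != names:
            raise ValidationError("plan CSV columns do not match the factor names")
    run_ids = tuple(int(r) for r in df["run"]) if "run" in df.columns else ()
    return ExperimentPlan(
        factors=factors, settings=df[names].to_numpy(dtype=float), run_ids=run_ids
    )
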