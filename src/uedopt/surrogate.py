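"""Polynomial response-surface surrogate over coded discrete factors.

The surrogate regresses the per-run mean response on a polynomial in
the coded factors,

    Y = a0 + sum_i a1i*Xi + sum_i a2i*Xi^2 + sum_i a3i*Xi^3
        + sum_{i<j} a4ij*Xi*Xj + eps,

where each factor's actual level values are affinely coded to [-1, +1]
(smallest level -> -1, largest -> +1).  With mixed 2/3-level factors
the full expansion is structurally rank-deficient: on two distinct
points x^2 and x^3 are affine in x, and on three distinct points x^3
lies in span{1, x, x^2} (Vandermonde), so quadratic and cubic terms of
2-level factors and cubic terms of 3-level factors are pruned before
fitting.  The remaining candidate set is still wider than the run
count, so terms enter by hierarchical forward stepwise selection under
a model-selection criterion (Mallows' Cp with replication pure error
when available, BIC otherwise), capped at n_runs - 2 terms;
coefficients are ordinary least squares on the selected columns.

`ResponseSurface` is the model object; `ResponseSurface.fit()` returns
a `ResponseSurfaceResults` carrying coefficients, diagnostics, a
`summary()` table, `predict()` and grid-search `recommend()`.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .allocation import ExperimentPlan, FactorSpec
from .exceptions import ValidationError
from .runner import ResponseTable, best_observed

__all__ = [
    "Term",
    "encode_factors",
    "decode_settings",
    "build_terms",
    "ResponseSurface",
    "ResponseSurfaceResults",
    "Recommendation",
    "ImprovementReport",
    "fit_surrogate",
    "predict",
    "recommend",
    "improvement_report",
]

_RSS_FLOOR = 1e-12  # guards log(RSS) once the fit is numerically exact


@dataclass(frozen=True)
class Term:
    """One column of the polynomial expansion.

    kind is one of ``intercept``, ``linear``, ``quadratic``, ``cubic``,
    ``interaction``; ``indices`` are the 0-based factor indices involved.
    """

    kind: str
    indices: tuple[int, ...]
    name: str

    def evaluate(self, coded: np.ndarray) -> np.ndarray:
        if self.kind == "intercept":
            return np.ones(coded.shape[0])
        if self.kind == "linear":
            return coded[:, self.indices[0]]
        if self.kind == "quadratic":
            return coded[:, self.indices[0]] ** 2
        if self.kind == "cubic":
            return coded[:, self.indices[0]] ** 3
        if self.kind == "interaction":
            i, j = self.indices
            return coded[:, i] * coded[:, j]
        raise ValueError(f"unknown term kind {self.kind!r}")


def _coding_maps(factors: Sequence[FactorSpec]) -> list[tuple[float, float]]:
    """Per-factor (lo, hi) actual values mapped to -1 and +1."""
    maps = []
    for f in factors:
        lo, hi = f.levels[0], f.levels[-1]
        if hi <= lo:
            raise ValidationError(f"factor {f.name!r} has a degenerate level range")
        maps.append((lo, hi))
    return maps


def _encode(values: np.ndarray, maps: Sequence[tuple[float, float]]) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for j, (lo, hi) in enumerate(maps):
        out[..., j] = -1.0 + 2.0 * (values[..., j] - lo) / (hi - lo)
    return out


def encode_factors(plan: ExperimentPlan) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Affinely code each factor column to [-1, +1]; returns (coded, maps).

    A factor whose settings column is constant across runs cannot be
    coded informatively and signals a degenerate design.
    """
    for j, f in enumerate(plan.factors):
        if np.unique(plan.settings[:, j]).size < 2:
            raise ValidationError(
                f"factor {f.name!r} is constant over the plan (degenerate design)"
            )
    maps = _coding_maps(plan.factors)
    return _encode(plan.settings, maps), maps


def decode_settings(coded: np.ndarray, maps: Sequence[tuple[float, float]]) -> np.ndarray:
    """Inverse of the [-1, +1] coding."""
    coded = np.asarray(coded, dtype=float)
    out = np.empty_like(coded)
    for j, (lo, hi) in enumerate(maps):
        out[..., j] = lo + (coded[..., j] + 1.0) * (hi - lo) / 2.0
    return out


def build_terms(
    coded: np.ndarray, factors: Sequence[FactorSpec], prune: bool = True
) -> tuple[np.ndarray, list[Term]]:
    """Expand coded factors into the polynomial term matrix.

    Full expansion (``prune=False``): intercept, Xi, Xi^2, Xi^3,
    XiXj (i<j).  Structural pruning (default) removes Xi^2 and Xi^3 for
    2-level factors and Xi^3 for 3-level factors, which are exactly
    collinear with lower-order terms on so few support points.
    """
    factors = tuple(factors)
    k = len(factors)
    terms: list[Term] = [Term("intercept", (), "1")]
    for i, f in enumerate(factors):
        terms.append(Term("linear", (i,), f.name))
    for i, f in enumerate(factors):
        if not prune or f.n_levels >= 3:
            terms.append(Term("quadratic", (i,), f"{f.name}^2"))
    for i, f in enumerate(factors):
        if not prune or f.n_levels >= 4:
            terms.append(Term("cubic", (i,), f"{f.name}^3"))
    for i, j in itertools.combinations(range(k), 2):
        terms.append(
            Term("interaction", (i, j), f"{factors[i].name}*{factors[j].name}")
        )
    matrix = np.column_stack([t.evaluate(coded) for t in terms])
    return matrix, terms


def _criterion(
    rss: float, n: int, k: int, which: str, noise_var: float | None = None
) -> float:
    """Model-selection criterion for an OLS fit with k mean coefficients.

    ``cp`` is Mallows' Cp with the error variance known externally (from
    replication pure error): RSS/sigma^2 + 2k, constants dropped.  The
    likelihood criteria count the estimated error variance as one extra
    parameter; AICc adds the small-sample correction and is infinite
    once its denominator closes (guards against saturation).
    """
    rss = max(rss, _RSS_FLOOR)
    if which == "cp":
        if noise_var is None:
            raise ValidationError("criterion 'cp' needs a pure-error noise variance")
        return rss / max(noise_var, _RSS_FLOOR) + 2 * k
    p = k + 1
    if which == "bic":
        return n * math.log(rss / n) + p * math.log(n)
    aic = n * math.log(rss / n) + 2 * p
    if which == "aic":
        return aic
    if which == "aicc":
        if n - p - 1 <= 0:
            return math.inf
        return aic + 2 * p * (p + 1) / (n - p - 1)
    raise ValidationError(f"unknown criterion {which!r}")


@dataclass(frozen=True)
class Recommendation:
    """Best factor combination over the full discrete level grid."""

    settings: tuple[float, ...]
    predicted_response: float
    grid_size: int
    factor_names: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "settings": dict(zip(self.factor_names, self.settings))
            if self.factor_names
            else list(self.settings),
            "predicted_response": self.predicted_response,
            "grid_size": self.grid_size,
        }


@dataclass(frozen=True)
class ImprovementReport:
    """Best in-design response vs. the confirmed response of the recommendation."""

    best_run_id: int
    best_observed: float
    confirmed_value: float
    improvement: float
    regressed: bool

    def __str__(self) -> str:
        lines = [
            f"best observed mean (run {self.best_run_id}): {self.best_observed:.2f}",
            f"confirmed recommended response:  {self.confirmed_value:.2f}",
            f"improvement:                     {self.improvement:+.2f}",
        ]
        if self.regressed:
            lines.append("WARNING: confirmed value is below the best observed run")
        return "\n".join(lines)


class ResponseSurface:
    """Polynomial response-surface model for an experiment plan.

    Parameters
    ----------
    plan : ExperimentPlan
        The runs and their factor settings.
    response : array-like, shape (n_runs,)
        Per-run mean response (percent).
    noise_variance : float, optional
        Pure-error variance of a run *mean*, estimated externally (for a
        replicated design, the mean within-run replicate variance divided
        by the replicate count).  Enables Mallows' Cp selection.
    """

    def __init__(
        self,
        plan: ExperimentPlan,
        response: Sequence[float],
        noise_variance: float | None = None,
    ) -> None:
        y = np.asarray(response, dtype=float)
        if y.shape != (plan.n_runs,):
            raise ValidationError("response length must equal the number of runs")
        if plan.n_runs < 3:
            raise ValidationError("need at least 3 runs to fit a surrogate")
        if noise_variance is not None and noise_variance < 0:
            raise ValidationError("noise_variance must be nonnegative")
        self.plan = plan
        self.response = y
        self.noise_variance = noise_variance
        self.coded, self.coding_maps = encode_factors(plan)
        self.term_matrix, self.terms = build_terms(self.coded, plan.factors)

    @classmethod
    def from_tables(cls, plan: ExperimentPlan, responses: ResponseTable) -> "ResponseSurface":
        if responses.plan is not plan and responses.plan.n_runs != plan.n_runs:
            raise ValidationError("response table does not match the plan")
        return cls.from_response_table(responses)

    @classmethod
    def from_response_table(cls, responses: ResponseTable) -> "ResponseSurface":
        """Build from a response table, using replication for pure error."""
        noise_var = None
        if responses.n_replicates >= 2:
            within = responses.replicates.var(axis=1, ddof=1).mean()
            noise_var = float(within / responses.n_replicates)
        return cls(responses.plan, responses.means, noise_variance=noise_var)

    def fit(
        self,
        max_terms: int | None = None,
        criterion: str | None = None,
    ) -> "ResponseSurfaceResults":
        """Hierarchical forward stepwise selection, then OLS on the result.

        The intercept is always kept.  The selection path grows greedily
        under effect hierarchy: linear terms are considered first, then
        pure quadratic/cubic terms, then pairwise interactions; within a
        tier the candidate giving the largest residual sum-of-squares
        reduction enters.  The path grows to ``max_terms`` (default
        ``n_runs - 2``) coefficients or a numerically exact fit, and the
        returned model is the prefix of the path minimizing the
        information criterion, so the search is not stranded at locally
        unfavourable sizes.  Candidates that would make the selected
        matrix rank-deficient are skipped.

        ``criterion`` defaults to Mallows' Cp when a pure-error noise
        variance is available (replicated designs) and BIC otherwise;
        ``"aic"``/``"aicc"``/``"bic"``/``"cp"`` may be forced.
        """
        if criterion is None:
            criterion = "cp" if self.noise_variance is not None else "bic"
        n = self.plan.n_runs
        if max_terms is None:
            max_terms = n - 2
        if max_terms > n - 2:
            raise ValidationError("max_terms cannot exceed n_runs - 2")
        if max_terms < 1:
            raise ValidationError("max_terms must be >= 1")
        X = self.term_matrix
        y = self.response
        tier_order = {"linear": 0, "quadratic": 1, "cubic": 1, "interaction": 2}
        tiers: list[list[int]] = [[], [], []]
        for i, t in enumerate(self.terms):
            if t.kind != "intercept":
                tiers[tier_order[t.kind]].append(i)
        selected = [0]  # intercept
        rss = float(np.sum((y - y.mean()) ** 2))
        path = [("1", _criterion(rss, n, 1, criterion, self.noise_variance), rss)]
        for tier in tiers:
            remaining = set(tier)
            while len(selected) < max_terms and remaining and rss > _RSS_FLOOR:
                best = None
                for c in sorted(remaining):
                    cols = selected + [c]
                    Xi = X[:, cols]
                    beta, res, rank, _ = np.linalg.lstsq(Xi, y, rcond=None)
                    if rank < len(cols):
                        remaining.discard(c)  # collinear with current selection
                        continue
                    r = (
                        float(res[0])
                        if res.size
                        else float(np.sum((y - Xi @ beta) ** 2))
                    )
                    if best is None or r < best[1] - 1e-12:
                        best = (c, r)
                if best is None:
                    break
                selected.append(best[0])
                remaining.discard(best[0])
                rss = best[1]
                path.append(
                    (self.terms[best[0]].name,
                     _criterion(rss, n, len(selected), criterion,
                                self.noise_variance), rss)
                )
        # choose the path prefix with the minimal criterion (first on ties)
        stop = min(range(len(path)), key=lambda i: (path[i][1], i))
        selected = selected[: stop + 1]
        path = path[: stop + 1]
        crit, rss = path[-1][1], path[-1][2]
        sel_terms = [self.terms[i] for i in selected]
        ols = sm.OLS(y, X[:, selected]).fit()
        return ResponseSurfaceResults(
            model=self,
            selected_terms=tuple(sel_terms),
            params=np.asarray(ols.params, dtype=float),
            rss=float(np.sum(ols.resid**2)),
            resid=np.asarray(ols.resid, dtype=float),
            criterion=criterion,
            criterion_value=float(crit),
            selection_path=tuple(path),
            ols_results=ols,
        )


@dataclass
class ResponseSurfaceResults:
    """Fitted surrogate: selected terms, coefficients and diagnostics."""

    model: ResponseSurface
    selected_terms: tuple[Term, ...]
    params: np.ndarray
    rss: float
    resid: np.ndarray
    criterion: str
    criterion_value: float
    selection_path: tuple[tuple[str, float, float], ...]
    ols_results: object | None = None

    @property
    def n_terms(self) -> int:
        return len(self.selected_terms)

    @property
    def coefficients(self) -> dict[str, float]:
        return {t.name: float(b) for t, b in zip(self.selected_terms, self.params)}

    def _expand(self, settings: np.ndarray) -> np.ndarray:
        coded = _encode(settings, self.model.coding_maps)
        return np.column_stack([t.evaluate(coded) for t in self.selected_terms])

    def predict(self, settings) -> float | np.ndarray:
        """Predicted response at one settings vector or a matrix of them."""
        arr = np.asarray(settings, dtype=float)
        single = arr.ndim == 1
        if single:
            arr = arr[None, :]
        if arr.shape[1] != self.model.plan.n_factors:
            raise ValidationError("settings length must match the factor count")
        for j, f in enumerate(self.model.plan.factors):
            if not np.isin(arr[:, j], f.levels).all():
                raise ValidationError(
                    f"settings contain a value outside factor {f.name!r} levels"
                )
        yhat = self._expand(arr) @ self.params
        return float(yhat[0]) if single else yhat

    def recommend(
        self, factors: Sequence[FactorSpec] | None = None, minimize: bool = False
    ) -> Recommendation:
        """Argmax (or argmin) of the prediction over the full level grid.

        Candidates are enumerated in lexicographic level order, and only
        a strictly better prediction replaces the incumbent, so ties
        resolve to the lexicographically smallest settings vector.
        """
        factors = tuple(factors) if factors is not None else self.model.plan.factors
        grid = np.array(list(itertools.product(*(f.levels for f in factors))))
        yhat = np.asarray(self.predict(grid), dtype=float)
        if minimize:
            yhat = -yhat
        best = 0
        for i in range(1, len(yhat)):
            if yhat[i] > yhat[best]:  # strict: keeps lexicographic tie-break
                best = i
        pred = self.predict(grid[best])
        return Recommendation(
            settings=tuple(float(v) for v in grid[best]),
            predicted_response=float(pred),
            grid_size=len(grid),
            factor_names=tuple(f.name for f in factors),
        )

    def summary(self) -> str:
        """Plain-text coefficient and diagnostics table."""
        lines = [
            "Response-surface surrogate (forward stepwise "
            f"{self.criterion.upper()}, OLS coefficients)",
            f"runs: {self.model.plan.n_runs}   candidate terms: "
            f"{len(self.model.terms)}   selected: {self.n_terms}",
            f"RSS: {self.rss:.6g}   {self.criterion.upper()}: "
            f"{self.criterion_value:.4f}",
            "-" * 46,
            f"{'term':<28}{'coefficient':>16}",
            "-" * 46,
        ]
        for t, b in zip(self.selected_terms, self.params):
            lines.append(f"{t.name:<28}{b:>16.6f}")
        lines.append("-" * 46)
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "uedopt.response_surface.v1",
            "criterion": self.criterion,
            "criterion_value": self.criterion_value,
            "rss": self.rss,
            "factors": [
                {"name": f.name, "levels": list(f.levels)}
                for f in self.model.plan.factors
            ],
            "coding_maps": [list(m) for m in self.model.coding_maps],
            "terms": [
                {"kind": t.kind, "indices": list(t.indices), "name": t.name,
                 "coefficient": float(b)}
                for t, b in zip(self.selected_terms, self.params)
            ],
            "selection_path": [
                {"term": name, "criterion": c, "rss": r}
                for name, c, r in self.selection_path
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_surrogate(
    plan: ExperimentPlan,
    responses: Sequence[float] | ResponseTable,
    max_terms: int | None = None,
    strategy: str | None = None,
) -> ResponseSurfaceResults:
    """Functional wrapper: build a :class:`ResponseSurface` and fit it.

    When ``responses`` is a :class:`ResponseTable` its replicates supply
    the pure-error variance, enabling the default Cp selection.
    """
    if isinstance(responses, ResponseTable):
        model = ResponseSurface.from_response_table(responses)
        if model.plan.n_runs != plan.n_runs:
            raise ValidationError("response table does not match the plan")
    else:
        model = ResponseSurface(plan, responses)
    return model.fit(max_terms=max_terms, criterion=strategy)


def predict(results: ResponseSurfaceResults, settings) -> float | np.ndarray:
    """Functional wrapper around :meth:`ResponseSurfaceResults.predict`."""
    return results.predict(settings)


def recommend(
    results: ResponseSurfaceResults,
    factors: Sequence[FactorSpec] | None = None,
    minimize: bool = False,
) -> Recommendation:
    """Functional wrapper around :meth:`ResponseSurfaceResults.recommend`."""
    return results.recommend(factors=factors, minimize=minimize)


def improvement_report(
    responses: ResponseTable, confirmed_value: float
) -> ImprovementReport:
    """Compare the confirmed recommended response with the best in-design run."""
    best = best_observed(responses)
    diff = float(confirmed_value) - best.mean
    return ImprovementReport(
        best_run_id=best.run_id,
        best_observed=best.mean,
        confirmed_value=float(confirmed_value),
        improvement=diff,
        regressed=diff < 0,
    )
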