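"""Experimental designs and response-surface statistics.

Designs
-------
* full factorial over arbitrary factor/level sets (lexicographic run order),
* one-factor-at-a-time (1-FAAT) concentration scans of a base medium,
* co-feed ratio x total-carbon grids.

Statistics
----------
* quadratic response-surface regression (linear + pairwise interaction +
  quadratic terms) with sequential backward elimination: refit, adjust the
  per-term p-values across the current non-intercept terms, drop the single
  worst term above alpha, repeat,
* per-condition screening against a control using the one-way-ANOVA pooled
  within-group variance for the contrasts,
* one-tailed Welch comparison of two samples.

Numeric factors are centred and scaled to [-1, 1] before fitting (standard
response-surface practice, and it keeps the normal equations well
conditioned); coefficients and optima are mapped back to natural units.
Categorical factors are effect-coded (sum-to-zero contrasts).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .blending import MediumSpec
from .errors import (
    EmptyFactor,
    MissingControl,
    RankDeficient,
    TooFewReplicates,
    TooFewRuns,
)

# SSR below this fraction of TSS counts as a perfect (noiseless) fit, where
# t statistics are 0/0; see _term_pvalues.
_PERFECT_FIT_RTOL = 1e-12
_ZERO_COEF_RTOL = 1e-8


# --- designs ------------------------------------------------------------


@dataclass
class FactorialDesign:
    """Full-factorial design: every combination of factor levels.

    Runs are enumerated lexicographically over factor-level indices, first
    factor slowest.
    """

    factors: list[tuple[str, list]]
    runs: list[tuple]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.runs, columns=[n for n, _ in self.factors])

    def __len__(self) -> int:
        return len(self.runs)


def full_factorial(factors: list[tuple[str, list]]) -> FactorialDesign:
    """Cartesian product of factor levels in lexicographic order."""
    if not factors:
        raise EmptyFactor("at least one factor is required")
    for name, levels in factors:
        if len(levels) < 2:
            raise EmptyFactor(f"factor {name!r} needs >= 2 levels, got {len(levels)}")
    runs = list(itertools.product(*[levels for _, levels in factors]))
    return FactorialDesign(factors=[(n, list(l)) for n, l in factors], runs=runs)


def ofaat_design(
    base: MediumSpec,
    factor: str,
    levels: list[float],
    unit: str | None = None,
) -> list[MediumSpec]:
    """One-factor-at-a-time scan: one medium per level, all else fixed.

    A level of 0 removes the item entirely (supplement-free control).  For
    an item not present in the base, ``unit`` must state its unit family.
    """
    if factor in base.targets:
        base_unit = base.targets[factor][1]
    elif unit is not None:
        base_unit = unit
    else:
        raise ValueError(f"item {factor!r} not in base medium; pass its unit family")
    media = []
    for level in levels:
        media.append(
            base.with_target(factor, level, base_unit, name=f"{base.name}[{factor}={level:g}]")
        )
    return media


def ratio_grid(
    substrates: tuple[str, str],
    ratios: list[tuple[float, float]],
    totals: list[float],
    include_pure: bool = False,
) -> list[dict]:
    """Co-feed grid: split each total amount between two substrates by ratio.

    For ratio (a, b) and total T the amounts are (T*a/(a+b), T*b/(a+b)).
    With ``include_pure``, single-substrate controls are appended per total.
    """
    s1, s2 = substrates
    out = []
    for total in totals:
        if not total > 0:
            raise ValueError("totals must be > 0")
        for a, b in ratios:
            if not (a > 0 and b > 0):
                raise ValueError("ratio parts must be > 0")
            out.append(
                {s1: total * a / (a + b), s2: total * b / (a + b),
                 "ratio": f"{a:g}:{b:g}", "total": total}
            )
        if include_pure:
            out.append({s1: total, s2: 0.0, "ratio": "pure_" + s1, "total": total})
            out.append({s1: 0.0, s2: total, "ratio": "pure_" + s2, "total": total})
    return out


# --- quadratic response model -------------------------------------------


@dataclass
class Term:
    """One model term: a named group of design-matrix columns.

    ``kind`` is intercept, linear, interaction or quadratic; ``factors``
    the factor name(s) involved.  Multi-column terms (effect-coded
    categoricals) carry one coefficient per column and an F-based p-value.
    """

    kind: str
    factors: tuple[str, ...]
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))
    column_labels: tuple[str, ...] = ()
    raw_p: float = math.nan
    adjusted_p: float = math.nan

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind == "quadratic":
            return f"{self.factors[0]}^2"
        return "*".join(self.factors)

    @property
    def coefficient(self) -> float:
        """Scalar coefficient (single-column terms only)."""
        return float(self.coefficients[0])

    @property
    def coef_magnitude(self) -> float:
        return float(np.max(np.abs(self.coefficients))) if len(self.coefficients) else 0.0


@dataclass
class _Coding:
    """How one factor is mapped into design-matrix columns."""

    name: str
    numeric: bool
    center: float = 0.0
    half_range: float = 1.0
    levels: tuple = ()  # categorical levels, first is the reference
    n_unique: int = 0

    def encode(self, values: pd.Series) -> np.ndarray:
        if self.numeric:
            return ((values.to_numpy(float) - self.center) / self.half_range)[:, None]
        cols = np.zeros((len(values), len(self.levels) - 1))
        vals = values.to_numpy()
        for j, level in enumerate(self.levels[1:]):
            cols[:, j] = np.where(vals == level, 1.0, np.where(vals == self.levels[0], -1.0, 0.0))
        return cols

    def labels(self) -> list[str]:
        if self.numeric:
            return [self.name]
        return [f"{self.name}[{lv}]" for lv in self.levels[1:]]


@dataclass
class ResponseModel:
    """Fitted quadratic response surface after backward elimination."""

    terms: list[Term]
    r_squared: float
    response_transform: str
    alpha: float
    codings: dict[str, _Coding]
    n_runs: int
    elimination_log: list[str] = field(default_factory=list)

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted response on the (possibly log) modelling scale."""
        X = np.column_stack(
            [_term_columns(t, data, self.codings) for t in self.terms]
        )
        beta = np.concatenate([t.coefficients for t in self.terms])
        return X @ beta

    def predict_response(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted response back on the measurement scale."""
        y = self.predict(data)
        return np.exp(y) if self.response_transform == "log" else y

    def natural_coefficients(self) -> dict[str, float]:
        """Polynomial coefficients in natural (uncoded) factor units.

        Only defined for all-numeric models: the coded polynomial is
        re-expanded in the original variables.  Keys are '1', 'a', 'a^2',
        'a*b'.
        """
        if any(not c.numeric for c in self.codings.values()):
            raise ValueError("natural coefficients are defined for numeric factors only")
        poly: dict[tuple, float] = {}

        def add(monomial: tuple, coef: float):
            poly[monomial] = poly.get(monomial, 0.0) + coef

        for t in self.terms:
            beta = t.coefficient if len(t.coefficients) else 0.0
            if t.kind == "intercept":
                add((), beta)
            elif t.kind == "linear":
                c = self.codings[t.factors[0]]
                add(((t.factors[0], 1),), beta / c.half_range)
                add((), -beta * c.center / c.half_range)
            elif t.kind == "quadratic":
                c = self.codings[t.factors[0]]
                h2 = c.half_range**2
                add(((t.factors[0], 2),), beta / h2)
                add(((t.factors[0], 1),), -2 * beta * c.center / h2)
                add((), beta * c.center**2 / h2)
            elif t.kind == "interaction":
                f1, f2 = t.factors
                c1, c2 = self.codings[f1], self.codings[f2]
                hh = c1.half_range * c2.half_range
                add(((f1, 1), (f2, 1)), beta / hh)
                add(((f1, 1),), -beta * c2.center / hh)
                add(((f2, 1),), -beta * c1.center / hh)
                add((), beta * c1.center * c2.center / hh)

        def key(monomial: tuple) -> str:
            if not monomial:
                return "1"
            return "*".join(f"{f}^{p}" if p > 1 else f for f, p in monomial)

        return {key(m): v for m, v in poly.items()}

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "kind": t.kind,
                    "coefficient": t.coef_magnitude if len(t.coefficients) > 1 else t.coefficient,
                    "raw_p": t.raw_p,
                    "adjusted_p": t.adjusted_p,
                }
                for t in self.terms
            ]
        )


def _candidate_terms(codings: dict[str, _Coding]) -> list[Term]:
    names = list(codings)
    terms = [Term(kind="intercept", factors=())]
    terms += [Term(kind="linear", factors=(n,)) for n in names]
    terms += [
        Term(kind="interaction", factors=(a, b))
        for a, b in itertools.combinations(names, 2)
    ]
    # a quadratic needs >= 3 distinct levels: with 2, z^2 is the intercept
    terms += [
        Term(kind="quadratic", factors=(n,))
        for n in names
        if codings[n].numeric and codings[n].n_unique >= 3
    ]
    return terms


def _term_columns(term: Term, data: pd.DataFrame, codings: dict[str, _Coding]) -> np.ndarray:
    n = len(data)
    if term.kind == "intercept":
        return np.ones((n, 1))
    if term.kind == "linear":
        return codings[term.factors[0]].encode(data[term.factors[0]])
    if term.kind == "quadratic":
        return codings[term.factors[0]].encode(data[term.factors[0]]) ** 2
    if term.kind == "interaction":
        a = codings[term.factors[0]].encode(data[term.factors[0]])
        b = codings[term.factors[1]].encode(data[term.factors[1]])
        return np.concatenate([a[:, i:i + 1] * b for i in range(a.shape[1])], axis=1)
    raise ValueError(term.kind)


def _make_codings(data: pd.DataFrame, factors: list[str]) -> dict[str, _Coding]:
    codings = {}
    for name in factors:
        col = data[name]
        if pd.api.types.is_numeric_dtype(col):
            lo, hi = float(col.min()), float(col.max())
            if hi == lo:
                raise EmptyFactor(f"factor {name!r} is constant")
            codings[name] = _Coding(
                name=name, numeric=True, center=(hi + lo) / 2,
                half_range=(hi - lo) / 2, n_unique=int(col.nunique()),
            )
        else:
            levels = tuple(pd.unique(col))
            if len(levels) < 2:
                raise EmptyFactor(f"factor {name!r} is constant")
            codings[name] = _Coding(
                name=name, numeric=False, levels=levels, n_unique=len(levels)
            )
    return codings


def _fit_ols(X: np.ndarray, y: np.ndarray):
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise RankDeficient(f"design matrix rank {rank} < {p} columns")
    resid = y - X @ beta
    ssr = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return beta, ssr, tss, np.linalg.inv(X.T @ X)


def _term_pvalues(
    terms: list[Term], beta: np.ndarray, ssr: float, tss: float,
    xtx_inv: np.ndarray, n: int, col_of: list[slice],
) -> None:
    """Per-term p-values: t test for single columns, F test for groups.

    On a numerically perfect fit the residual variance is 0 and every t
    statistic is 0/0; the well-defined limit is p -> 0 for a term with a
    non-zero coefficient and p -> 1 for an exactly-zero one, which is what
    noiseless oracle data require.
    """
    p_total = sum(len(t.coefficients) for t in terms)
    df = n - p_total
    scale = max(np.max(np.abs(beta)), 1e-300)
    perfect = ssr <= _PERFECT_FIT_RTOL * max(tss, 1.0)
    mse = ssr / df if df > 0 else math.inf
    for t, sl in zip(terms, col_of):
        if t.kind == "intercept":
            t.raw_p = math.nan
            continue
        b = beta[sl]
        if perfect or df <= 0:
            t.raw_p = 0.0 if np.max(np.abs(b)) > _ZERO_COEF_RTOL * scale else 1.0
            continue
        cov = mse * xtx_inv[sl, sl]
        if len(b) == 1:
            se = math.sqrt(cov[0, 0])
            tstat = b[0] / se if se > 0 else math.inf * np.sign(b[0])
            t.raw_p = 2 * stats.t.sf(abs(tstat), df)
        else:
            fstat = float(b @ np.linalg.solve(cov, b)) / len(b)
            t.raw_p = float(stats.f.sf(fstat, len(b), df))


def _adjust(pvals: list[float], method: str) -> list[float]:
    if not pvals:
        return []
    if method == "none":
        return list(pvals)
    key = {"bh": "fdr_bh", "holm": "holm"}[method]
    return list(multipletests(pvals, method=key)[1])


def fit_quadratic(
    data: pd.DataFrame,
    response,
    factors: list[str] | None = None,
    transform: str = "identity",
    alpha: float = 0.01,
    adjust: str = "bh",
    enforce_hierarchy: bool = False,
) -> ResponseModel:
    """Fit a quadratic surface and prune it by sequential backward elimination.

    Parameters
    ----------
    data : DataFrame with one row per run and one column per factor
        (numeric or categorical).
    response : column name in ``data`` or an array of measurements.
    transform : 'identity' or 'log' (growth-type endpoints are usually
        modelled on the log scale).
    alpha : significance threshold for retained terms (adjusted p).
    adjust : multiplicity adjustment across the current non-intercept
        terms: 'bh' (Benjamini-Hochberg), 'holm' or 'none'.
    enforce_hierarchy : when True a linear term is not dropped while a
        higher-order term involving its factor remains.

    The elimination loop fits ordinary least squares on the current terms,
    adjusts the per-term p-values, removes the single term with the
    largest adjusted p above alpha, and refits, stopping when every
    remaining term passes (or only the intercept is left).
    """
    if isinstance(response, str):
        y = data[response].to_numpy(float)
        factor_names = factors or [c for c in data.columns if c != response]
    else:
        y = np.asarray(response, float)
        factor_names = factors or list(data.columns)
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive responses")
        y = np.log(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    if adjust not in ("bh", "holm", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    codings = _make_codings(data, factor_names)
    terms = _candidate_terms(codings)
    n = len(y)
    p_cols = sum(_term_columns(t, data.iloc[:1], codings).shape[1] for t in terms)
    if n < p_cols + 2:
        raise TooFewRuns(f"{n} runs cannot support {p_cols} candidate columns (+2)")

    log: list[str] = []
    max_iter = len(terms)
    for _ in range(max_iter + 1):
        blocks = [_term_columns(t, data, codings) for t in terms]
        col_of, start = [], 0
        for b in blocks:
            col_of.append(slice(start, start + b.shape[1]))
            start += b.shape[1]
        X = np.concatenate(blocks, axis=1)
        beta, ssr, tss, xtx_inv = _fit_ols(X, y)
        for t, sl in zip(terms, col_of):
            t.coefficients = beta[sl].copy()
            t.column_labels = tuple(
                lbl for f in t.factors for lbl in codings[f].labels()
            ) if t.kind != "intercept" else ("intercept",)
        _term_pvalues(terms, beta, ssr, tss, xtx_inv, n, col_of)

        non_int = [t for t in terms if t.kind != "intercept"]
        adj = _adjust([t.raw_p for t in non_int], adjust)
        for t, a in zip(non_int, adj):
            t.adjusted_p = a

        droppable = non_int
        if enforce_hierarchy:
            protected = set()
            for t in non_int:
                if t.kind in ("quadratic", "interaction"):
                    protected.update(t.factors)
            droppable = [
                t for t in non_int
                if not (t.kind == "linear" and t.factors[0] in protected)
            ]
        failing = [t for t in droppable if t.adjusted_p > alpha]
        if not failing:
            break
        worst = max(failing, key=lambda t: (t.adjusted_p, -t.coef_magnitude))
        log.append(f"dropped {worst.name} (adjusted p = {worst.adjusted_p:.4g})")
        terms = [t for t in terms if t is not worst]

    r2 = 1.0 - ssr / tss if tss > 0 else 0.0
    return ResponseModel(
        terms=terms,
        r_squared=r2,
        response_transform=transform,
        alpha=alpha,
        codings=codings,
        n_runs=n,
        elimination_log=log,
    )


def rank_effects(model: ResponseModel) -> list[Term]:
    """Non-intercept terms by ascending adjusted p; ties by |coef| desc, name."""
    return sorted(
        (t for t in model.terms if t.kind != "intercept"),
        key=lambda t: (
            t.adjusted_p if not math.isnan(t.adjusted_p) else math.inf,
            -t.coef_magnitude,
            t.name,
        ),
    )


def optimum_on_surface(
    model: ResponseModel,
    bounds: dict[str, tuple[float, float]],
    grid_points: int = 201,
) -> tuple[dict[str, float], float, bool]:
    """Maximise the fitted surface on a box; returns (location, value, on_boundary).

    Dense-grid search with >= ``grid_points`` per axis (full mesh up to 3
    factors, coordinate-ascent sweeps above that), refined analytically for
    a pure one-dimensional parabola.  The predicted value is reported on
    the measurement scale; a maximum sitting on the box boundary is flagged
    rather than treated as an error.
    """
    if any(not c.numeric for c in model.codings.values()):
        raise ValueError("surface optimisation requires numeric factors only")
    names = [n for n in model.codings if n in bounds]
    if set(bounds) != set(model.codings):
        raise ValueError("bounds must cover exactly the model's factors")
    axes = [np.linspace(bounds[n][0], bounds[n][1], grid_points) for n in names]

    if len(names) <= 3:
        mesh = np.meshgrid(*axes, indexing="ij")
        df = pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})
        yhat = model.predict(df)
        i = int(np.argmax(yhat))
        best = {n: float(df[n].iloc[i]) for n in names}
    else:
        best = {n: float((bounds[n][0] + bounds[n][1]) / 2) for n in names}
        for _ in range(8):
            moved = False
            for n, ax in zip(names, axes):
                df = pd.DataFrame({m: np.full(grid_points, best[m]) for m in names})
                df[n] = ax
                yhat = model.predict(df)
                cand = float(ax[int(np.argmax(yhat))])
                if cand != best[n]:
                    best[n] = cand
                    moved = True
            if not moved:
                break

    # analytic vertex for a pure 1-D parabola
    if len(names) == 1:
        name = names[0]
        kinds = {t.kind for t in model.terms}
        if kinds <= {"intercept", "linear", "quadratic"}:
            b = next((t.coefficient for t in model.terms if t.kind == "linear"), 0.0)
            c2 = next((t.coefficient for t in model.terms if t.kind == "quadratic"), 0.0)
            if c2 < 0:
                coding = model.codings[name]
                vertex = coding.center + coding.half_range * (-b / (2 * c2))
                lo, hi = bounds[name]
                best[name] = float(min(max(vertex, lo), hi))

    on_boundary = any(
        math.isclose(best[n], bounds[n][0], rel_tol=0, abs_tol=1e-9 * (1 + abs(bounds[n][0])))
        or math.isclose(best[n], bounds[n][1], rel_tol=0, abs_tol=1e-9 * (1 + abs(bounds[n][1])))
        for n in names
    )
    value = float(model.predict_response(pd.DataFrame({n: [best[n]] for n in names}))[0])
    return best, value, on_boundary


# --- screening ----------------------------------------------------------


@dataclass
class ScreenEffect:
    label: str
    mean_ratio: float
    raw_p: float
    adjusted_p: float
    direction: str  # beneficial | detrimental | null


@dataclass
class ScreenResult:
    """Per-condition comparison against a shared control."""

    control_label: str
    effects: dict[str, ScreenEffect]
    omnibus_f: float
    omnibus_p: float
    alpha: float

    def labelled(self, direction: str) -> list[str]:
        return [l for l, e in self.effects.items() if e.direction == direction]


def screen_vs_control(
    data: dict[str, list[float]],
    control_label: str,
    alpha: float = 0.02,
    adjust: str = "bh",
    transform: str = "identity",
) -> ScreenResult:
    """Screen conditions against a control within a one-way ANOVA frame.

    Each condition is compared to the control with a two-sided t contrast
    using the pooled within-group variance across *all* conditions (the
    one-way-ANOVA mean square error, df = N - k), and p-values are
    adjusted across conditions.  Effects with adjusted p < alpha are
    labelled beneficial or detrimental by the sign of the mean difference;
    the omnibus F is reported alongside for transparency.
    """
    if control_label not in data:
        raise MissingControl(f"control {control_label!r} absent from screen data")
    groups = {}
    for label, values in data.items():
        arr = np.asarray(values, float)
        if len(arr) < 2:
            raise TooFewReplicates(f"condition {label!r} has {len(arr)} replicates (< 2)")
        if transform == "log":
            if np.any(arr <= 0):
                raise ValueError("log transform requires positive measurements")
            groups[label] = np.log(arr)
        else:
            groups[label] = arr

    all_groups = list(groups.values())
    n_total = sum(len(g) for g in all_groups)
    k = len(all_groups)
    df_resid = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in all_groups) / df_resid
    fstat, fp = stats.f_oneway(*all_groups)

    ctrl = groups[control_label]
    ctrl_mean_raw = float(np.mean(data[control_label]))
    labels, raws, diffs = [], [], []
    for label, g in groups.items():
        if label == control_label:
            continue
        diff = g.mean() - ctrl.mean()
        se = math.sqrt(mse * (1 / len(g) + 1 / len(ctrl)))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = 2 * stats.t.sf(abs(diff) / se, df_resid)
        labels.append(label)
        raws.append(float(p))
        diffs.append(float(diff))
    adj = _adjust(raws, adjust)

    effects = {}
    for label, raw, a, diff in zip(labels, raws, adj, diffs):
        if a < alpha and diff != 0:
            direction = "beneficial" if diff > 0 else "detrimental"
        else:
            direction = "null"
        effects[label] = ScreenEffect(
            label=label,
            mean_ratio=float(np.mean(data[label])) / ctrl_mean_raw,
            raw_p=raw,
            adjusted_p=a,
            direction=direction,
        )
    return ScreenResult(
        control_label=control_label,
        effects=effects,
        omnibus_f=float(fstat),
        omnibus_p=float(fp),
        alpha=alpha,
    )


def welch_one_tailed(
    sample_a, sample_b, alternative: str = "b_greater"
) -> float:
    """One-tailed Welch's t test between two samples.

    ``alternative`` states the hypothesis: 'b_greater' tests
    mean(b) > mean(a), 'a_greater' the reverse.  Complementary directions
    on the same data sum to 1.  Zero-variance degenerate samples are
    resolved by direct mean comparison (p = 0, 0.5 or 1).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise TooFewReplicates("Welch test needs >= 2 values per sample")
    if alternative not in ("b_greater", "a_greater"):
        raise ValueError("alternative must be 'b_greater' or 'a_greater'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        diff = b.mean() - a.mean()
        if diff == 0:
            return 0.5
        favourable = diff > 0 if alternative == "b_greater" else diff < 0
        return 0.0 if favourable else 1.0
    scipy_alt = "less" if alternative == "b_greater" else "greater"
    return float(stats.ttest_ind(a, b, equal_var=False, alternative=scipy_alt).pvalue)


def welch_statistic(sample_a, sample_b) -> tuple[float, float]:
    """Welch t statistic (b vs a) and Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (b.mean() - a.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(t), float(df)
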