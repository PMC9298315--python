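"""Greedy round-based media optimization.

Starting from a basal medium, each round runs three stages against an
abstract phenotype evaluator (a simulator or a wet-lab import adapter):

1. **supplement screen** — the base medium plus each library supplement at
   its screening concentration, compared against the unsupplemented
   control; beneficial and detrimental supplements are identified, and
   detrimental ones are dropped from the library.
2. **combination screen** — each beneficial supplement alone and every
   unordered pair, ranked by mean measurement; the top combination is
   accepted into the medium if a one-tailed Welch test against the
   incumbent passes.
3. **concentration optimization** — the concentrations of the newly
   accepted items (plus any configured base components) are scanned
   (1-FAAT by default, or a full-factorial surface fit) and the medium
   moves to the best level only if its evaluated mean beats the incumbent.

Rounds repeat until a target specification is met, the library is
exhausted, a full round accepts no change, or the round limit is reached.
The accepted medium's evaluated mean is non-decreasing across rounds by
construction, and every evaluation is recorded in the audit log.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Protocol

import numpy as np
import pandas as pd

from .blending import Constraints, MediumSpec, solve_blend
from .doe import full_factorial, ofaat_design, fit_quadratic, optimum_on_surface, screen_vs_control, welch_one_tailed
from .errors import MediablendError, MissingPlan
from .registry import StockRegistry
from .simulate import ResponseSurfaceTruth, evaluate

LIBRARY_CSV_COLUMNS = [
    "supplement_name",
    "stock_name",
    "screening_concentration",
    "unit",
    "category",
]

CATEGORIES = (
    "amino_acid", "trace_metal", "vitamin", "lipid", "surfactant",
    "chaperone", "antioxidant", "chelator", "carbon_cofeed", "other",
)


class Evaluator(Protocol):
    """Phenotype evaluator contract.

    Given media and a replicate count, returns exactly ``n_replicates``
    positive measurements per medium, keyed by medium name.  Must support
    repeated calls; ``seed`` controls any stochasticity.
    """

    def measure(
        self, media: list[MediumSpec], n_replicates: int, seed: int
    ) -> dict[str, list[float]]: ...


class SimulatorEvaluator:
    """Evaluator backed by a synthetic ground-truth landscape."""

    def __init__(self, truth: ResponseSurfaceTruth):
        self.truth = truth

    def measure(self, media, n_replicates, seed):
        return {
            m.name: [r.value for r in evaluate(self.truth, m, n_replicates, replicate_seed=seed)]
            for m in media
        }


class TableEvaluator:
    """Evaluator backed by recorded measurements (wet-lab import adapter).

    Expects the measurements table shape: columns medium_name, replicate,
    value (plate_id/well ignored).
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def measure(self, media, n_replicates, seed):
        out = {}
        for m in media:
            rows = self.table[self.table["medium_name"] == m.name]
            if len(rows) < n_replicates:
                raise MissingPlan(
                    f"measurements table has {len(rows)} rows for {m.name!r}, "
                    f"need {n_replicates}"
                )
            out[m.name] = rows["value"].astype(float).tolist()[:n_replicates]
        return out


@dataclass(frozen=True)
class LibraryEntry:
    """One screening-library candidate: which item to add, at what dose."""

    supplement_name: str
    stock_name: str
    screening_concentration: float
    unit: str
    category: str = "other"


def read_library_csv(path) -> list[LibraryEntry]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(LIBRARY_CSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"library csv missing columns: {sorted(missing)}")
    return [
        LibraryEntry(
            supplement_name=r["supplement_name"],
            stock_name=r["stock_name"],
            screening_concentration=float(r["screening_concentration"]),
            unit=r["unit"],
            category=r.get("category", "other") or "other",
        )
        for _, r in df.iterrows()
    ]


@dataclass
class StageRecord:
    round_index: int
    stage: str  # supplement_screen | combination_screen | concentration_opt
    candidates: list[str]
    decision: str
    measurements: dict[str, list[float]]
    details: dict = field(default_factory=dict)


@dataclass
class OptimizationState:
    current_medium: MediumSpec
    best_mean: float
    best_sd: float
    best_n: int
    round_log: list[StageRecord] = field(default_factory=list)
    stop_reason: str | None = None
    excluded: set = field(default_factory=set)  # detrimental or incorporated

    def record(self, rec: StageRecord) -> None:
        self.round_log.append(rec)

    def accept(self, medium: MediumSpec, values: list[float]) -> None:
        self.current_medium = medium
        self.best_mean = float(np.mean(values))
        self.best_sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        self.best_n = len(values)


@dataclass
class OptimizerConfig:
    n_replicates: int = 3
    alpha_screen: float = 0.02
    alpha_accept: float = 0.05
    adjust: str = "bh"
    transform: str = "log"  # screen scale; log suits growth-type endpoints
    max_rounds: int = 3
    target_spec: float | None = None
    strategy: str = "ofaat"  # or full_factorial
    level_multipliers: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    levels_per_item: dict = field(default_factory=dict)  # absolute levels override
    tune_items: tuple = ()  # base components always concentration-optimized
    rescreen_all: bool = False  # re-screen detrimental/incorporated each round
    pairwise_only: bool = True
    seed: int = 0
    constraints: Constraints = field(default_factory=Constraints)


def _seed_stream(seed: int):
    counter = itertools.count()
    def next_seed() -> int:
        return (seed * 1_000_003 + 7919 * next(counter)) % 2**31
    return next_seed


def _supplemented(base: MediumSpec, entries: tuple[LibraryEntry, ...], name: str) -> MediumSpec:
    medium = base
    for e in entries:
        medium = medium.with_target(e.stock_name, e.screening_concentration, e.unit, name=name)
    # ensure the name sticks even when entries is empty
    return MediumSpec(name=name, targets=dict(medium.targets), fill_volume_ul=medium.fill_volume_ul)


def _feasible(medium: MediumSpec, registry: StockRegistry | None, constraints: Constraints) -> bool:
    if registry is None:
        return True
    try:
        solve_blend(medium, registry, constraints)
        return True
    except MediablendError:
        return False


def run_supplement_stage(
    state: OptimizationState,
    library: list[LibraryEntry],
    evaluator: Evaluator,
    config: OptimizerConfig,
    round_index: int,
    seed: int,
    registry: StockRegistry | None = None,
) -> list[LibraryEntry]:
    """Screen each library supplement singly against the current medium.

    Returns the beneficial entries; detrimental (and, unless
    ``rescreen_all``, already screened-out) supplements are added to
    ``state.excluded``.  Infeasible candidates are logged and skipped.
    """
    candidates = [e for e in library if e.supplement_name not in state.excluded]
    if not candidates:
        state.stop_reason = "library_exhausted"
        state.record(StageRecord(round_index, "supplement_screen", [], "library empty", {}))
        return []

    base = state.current_medium
    media, skipped = [base], []
    label_of = {}
    for e in candidates:
        m = _supplemented(base, (e,), f"{base.name}+{e.supplement_name}")
        if not _feasible(m, registry, config.constraints):
            skipped.append(e.supplement_name)
            continue
        media.append(m)
        label_of[m.name] = e
    data = evaluator.measure(media, config.n_replicates, seed)
    screen = screen_vs_control(
        data, base.name, alpha=config.alpha_screen,
        adjust=config.adjust, transform=config.transform,
    )
    beneficial = [label_of[l] for l in screen.labelled("beneficial")]
    detrimental = [label_of[l] for l in screen.labelled("detrimental")]
    for e in detrimental:
        state.excluded.add(e.supplement_name)
    state.record(
        StageRecord(
            round_index, "supplement_screen",
            [e.supplement_name for e in candidates],
            f"beneficial={[e.supplement_name for e in beneficial]} "
            f"detrimental={[e.supplement_name for e in detrimental]}",
            data,
            details={
                "skipped_infeasible": skipped,
                "adjusted_p": {l: eff.adjusted_p for l, eff in screen.effects.items()},
                "omnibus_p": screen.omnibus_p,
            },
        )
    )
    return beneficial


def run_combination_stage(
    state: OptimizationState,
    beneficial: list[LibraryEntry],
    evaluator: Evaluator,
    config: OptimizerConfig,
    round_index: int,
    seed: int,
    registry: StockRegistry | None = None,
) -> tuple[LibraryEntry, ...] | None:
    """Rank single supplements and unordered pairs; accept the winner.

    The top-ranked combination is accepted into the medium when a
    one-tailed Welch test against the incumbent's measurements passes at
    ``alpha_accept`` (and its mean is strictly higher).  Returns the
    accepted combination, or None.
    """
    if not beneficial:
        return None
    combos: list[tuple[LibraryEntry, ...]] = [(e,) for e in beneficial]
    if len(beneficial) > 1:
        combos += [tuple(p) for p in itertools.combinations(beneficial, 2)]

    base = state.current_medium
    media = [base]
    combo_of = {}
    for combo in combos:
        label = "+".join(e.supplement_name for e in combo)
        m = _supplemented(base, combo, f"{base.name}+{label}")
        if not _feasible(m, registry, config.constraints):
            continue
        media.append(m)
        combo_of[m.name] = (combo, m)
    data = evaluator.measure(media, config.n_replicates, seed)
    ranking = sorted(
        (name for name in data if name != base.name),
        key=lambda name: -float(np.mean(data[name])),
    )
    decision = "no feasible combination"
    accepted = None
    if ranking:
        top = ranking[0]
        combo, medium = combo_of[top]
        p = welch_one_tailed(data[base.name], data[top], alternative="b_greater")
        # the incumbent's recorded best mean keeps acceptance monotone even
        # when the stage-local control arm drew low
        if p < config.alpha_accept and np.mean(data[top]) > state.best_mean:
            state.accept(medium, data[top])
            for e in combo:
                state.excluded.add(e.supplement_name)  # incorporated
            accepted = combo
            decision = f"accepted {top} (welch p = {p:.3g})"
        else:
            decision = f"kept incumbent (top {top}, welch p = {p:.3g})"
    details = {"ranking": ranking}
    if accepted is not None:
        details["accepted_mean"] = state.best_mean
    state.record(
        StageRecord(
            round_index, "combination_screen",
            list(combo_of), decision, data, details=details,
        )
    )
    return accepted


def _scan_levels(item: str, current: float, config: OptimizerConfig) -> list[float]:
    if item in config.levels_per_item:
        return list(config.levels_per_item[item])
    return [current * m for m in config.level_multipliers]


def run_concentration_stage(
    state: OptimizationState,
    items: list[str],
    evaluator: Evaluator,
    config: OptimizerConfig,
    round_index: int,
    seed_stream,
    registry: StockRegistry | None = None,
) -> bool:
    """Optimize the concentration of each chosen item; greedy acceptance.

    1-FAAT strategy scans each item over its levels with everything else
    fixed; the best level replaces the incumbent only if its evaluated
    mean is strictly higher.  The full-factorial strategy fits a quadratic
    surface over all items jointly and evaluates the predicted optimum.
    Returns True when any change was accepted.
    """
    changed = False
    items = [i for i in items if i in state.current_medium.targets]
    if not items:
        return False

    if config.strategy == "full_factorial" and len(items) >= 2:
        base = state.current_medium
        levels = {i: _scan_levels(i, base.targets[i][0], config) for i in items}
        design = full_factorial([(i, levels[i]) for i in items])
        df = design.to_dataframe()
        media = []
        for r, run in enumerate(design.runs):
            m = base
            for i, lv in zip(items, run):
                m = m.with_target(i, lv, base.targets[i][1], name=f"{base.name}|run{r}")
            media.append(m)
        media = [m for m in media if _feasible(m, registry, config.constraints)]
        data = evaluator.measure(media + [base], config.n_replicates, seed_stream())
        y = np.array([np.mean(data[m.name]) for m in media])
        kept = [m.name for m in media]
        df = df.iloc[: len(media)]
        model = fit_quadratic(df, y, transform=config.transform, alpha=0.05)
        bounds = {i: (min(levels[i]), max(levels[i])) for i in items}
        loc, _pred, _flag = optimum_on_surface(model, bounds)
        cand = base
        for i in items:
            cand = cand.with_target(i, loc[i], base.targets[i][1],
                                    name=f"{base.name}|opt")
        check = evaluator.measure([cand, base], config.n_replicates, seed_stream())
        decision = "kept incumbent (no gain)"
        details = {"optimum": loc}
        if np.mean(check[cand.name]) > state.best_mean:
            state.accept(cand, check[cand.name])
            changed = True
            decision = f"moved to surface optimum {loc}"
            details["accepted_mean"] = state.best_mean
        state.record(
            StageRecord(round_index, "concentration_opt", kept, decision,
                        {**data, **check}, details=details)
        )
        return changed

    for item in items:
        base = state.current_medium
        current, unit = base.targets[item]
        levels = [lv for lv in _scan_levels(item, current, config) if lv > 0]
        media = ofaat_design(base, item, levels)
        media = [m for m in media if _feasible(m, registry, config.constraints)]
        data = evaluator.measure(media + [base], config.n_replicates, seed_stream())
        ranked = sorted(media, key=lambda m: -float(np.mean(data[m.name])))
        decision = "kept incumbent (no gain)"
        details = {"item": item, "levels": levels}
        if ranked:
            top = ranked[0]
            best_level = top.targets.get(item, (0.0, unit))[0]
            is_change = abs(best_level - current) > 1e-9 * max(abs(current), 1e-12)
            if is_change and float(np.mean(data[top.name])) > state.best_mean:
                accepted = base.with_target(item, best_level, unit)
                state.accept(accepted, data[top.name])
                changed = True
                decision = f"{item} -> {best_level:g} {unit}"
                details["accepted_mean"] = state.best_mean
        state.record(
            StageRecord(round_index, "concentration_opt",
                        [m.name for m in media], decision, data,
                        details=details)
        )
    return changed


def optimize(
    base: MediumSpec,
    library: list[LibraryEntry],
    evaluator: Evaluator,
    config: OptimizerConfig | None = None,
    registry: StockRegistry | None = None,
) -> OptimizationState:
    """Run the full supplement -> combination -> concentration loop.

    Stops when the target specification is met, the library is exhausted
    with nothing left to tune, a full round accepts no change, or
    ``max_rounds`` is reached.  The returned state carries the complete
    audit log; identical inputs and seed reproduce it exactly.
    """
    config = config or OptimizerConfig()
    next_seed = _seed_stream(config.seed)

    baseline = evaluator.measure([base], config.n_replicates, next_seed())[base.name]
    state = OptimizationState(
        current_medium=base,
        best_mean=float(np.mean(baseline)),
        best_sd=float(np.std(baseline, ddof=1)) if len(baseline) > 1 else 0.0,
        best_n=len(baseline),
    )
    state.record(
        StageRecord(0, "baseline", [base.name], f"baseline mean {state.best_mean:.4g}",
                    {base.name: baseline})
    )
    if config.target_spec is not None and state.best_mean >= config.target_spec:
        state.stop_reason = "spec_met"
        return state

    for round_index in range(1, config.max_rounds + 1):
        changed = False
        if config.rescreen_all:
            state.excluded = {
                e.supplement_name for e in library
                if e.stock_name in state.current_medium.targets
            }
        remaining = [e for e in library if e.supplement_name not in state.excluded]
        ran_anything = False

        chosen_items: list[str] = []
        if remaining:
            ran_anything = True
            beneficial = run_supplement_stage(
                state, library, evaluator, config, round_index, next_seed(), registry
            )
            if beneficial:
                accepted = run_combination_stage(
                    state, beneficial, evaluator, config, round_index, next_seed(), registry
                )
                if accepted:
                    changed = True
                    chosen_items = [e.stock_name for e in accepted]

        tune = chosen_items + [i for i in config.tune_items if i not in chosen_items]
        if tune:
            ran_anything = True
            if run_concentration_stage(
                state, tune, evaluator, config, round_index, next_seed, registry
            ):
                changed = True

        if config.target_spec is not None and state.best_mean >= config.target_spec:
            state.stop_reason = "spec_met"
            break
        if not ran_anything:
            state.stop_reason = "library_exhausted"
            break
        if not changed:
            state.stop_reason = "no_gain"
            break
    else:
        state.stop_reason = "max_rounds"
    return state


# --- audit log serialization -------------------------------------------


def log_to_jsonl(state: OptimizationState, path=None) -> str:
    """One JSON record per stage decision (plus a final summary line)."""
    lines = []
    for rec in state.round_log:
        lines.append(json.dumps({
            "round": rec.round_index,
            "stage": rec.stage,
            "candidates": rec.candidates,
            "decision": rec.decision,
            "measurements": {k: list(map(float, v)) for k, v in rec.measurements.items()},
            "details": _jsonable(rec.details),
        }, sort_keys=True))
    lines.append(json.dumps({
        "final_medium": state.current_medium.name,
        "targets": {k: list(v) for k, v in state.current_medium.targets.items()},
        "best_mean": state.best_mean,
        "best_sd": state.best_sd,
        "best_n": state.best_n,
        "stop_reason": state.stop_reason,
    }, sort_keys=True))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if not isinstance(obj, (list, tuple))] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
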