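"""Self-contained benchmark studies of the solver, screen and optimizer.

Each study builds its own inputs, runs the package, and measures the
result against an independent reference (a closed-form recomputation or
the simulator's noise-free ground truth).  They quantify, on synthetic
landscapes, how reliably the pipeline recovers what was planted:

* :func:`dm2_fold_concentration` — worked fold-concentration example for a
  production-style medium whose stocks occupy 31% of the well (69% water).
* :func:`solver_oracle_study` — randomized feasible media vs the C_t*V/C_s
  dilution closed form.
* :func:`quadratic_recovery_study` — noiseless in-model surfaces over the
  classic 3x2x3 and 3^4 factorial shapes.
* :func:`screen_recovery_study` — operating characteristics of the
  supplement screen (16 supplements, 5 beneficial at +50%).
* :func:`optimizer_recovery_study` — end-to-end greedy optimization on a
  planted landscape with a synergistic supplement pair and a peaked base
  component.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from .blending import Constraints, MediumSpec, max_fold_concentration, solve_blend, water_fraction
from .doe import fit_quadratic, full_factorial, screen_vs_control
from .optimize import (
    LibraryEntry,
    OptimizerConfig,
    SimulatorEvaluator,
    optimize,
)
from .registry import Component, StockRegistry, StockSolution
from .simulate import (
    ComponentEffect,
    ResponseSurfaceTruth,
    TruthConfig,
    boost_effect,
    evaluate,
    make_truth,
    supplement_name,
)


# --- worked fold-concentration example ----------------------------------


def dm2_style_registry() -> StockRegistry:
    """Stocks for a methanol-induction production medium.

    Composition mirrors a defined production medium: 2x YNB, 2 v/v%
    methanol, 20 g/L sorbitol co-feed, 1 g/L urea, 4 g/L potassium
    phosphate buffer and 1x of a cholesterol-rich lipid supplement.
    """
    reg = StockRegistry()
    for comp, unit in [
        ("YNB", "fold"), ("methanol", "v_v_percent"), ("sorbitol", "g_per_L"),
        ("urea", "g_per_L"), ("potassium phosphate", "g_per_L"),
        ("cholesterol supplement", "fold"),
    ]:
        reg.add_component(Component(name=comp, unit_family=unit))
    reg.register_stock(StockSolution("YNB 10x", {"YNB": 10}))
    reg.register_stock(StockSolution("methanol 50%", {"methanol": 50}))
    reg.register_stock(StockSolution("sorbitol 500", {"sorbitol": 500}))
    reg.register_stock(StockSolution("urea 100", {"urea": 100}))
    reg.register_stock(StockSolution("phosphate 400", {"potassium phosphate": 400}))
    reg.register_stock(StockSolution("cholesterol 100x", {"cholesterol supplement": 100}))
    return reg


def dm2_style_medium(fill_volume_ul: float = 1000.0) -> MediumSpec:
    return MediumSpec(
        name="DM2_style",
        targets={
            "YNB": (2, "fold"),
            "methanol": (2, "v_v_percent"),
            "sorbitol": (20, "g_per_L"),
            "urea": (1, "g_per_L"),
            "potassium phosphate": (4, "g_per_L"),
            "cholesterol supplement": (1, "fold"),
        },
        fill_volume_ul=fill_volume_ul,
    )


def dm2_fold_concentration() -> dict:
    """Water fraction and maximal fold-concentration of the worked medium."""
    plan = solve_blend(dm2_style_medium(), dm2_style_registry())
    factor, integer = max_fold_concentration(plan)
    return {
        "water_fraction": water_fraction(plan),
        "fold_factor": factor,
        "fold_integer": integer,
    }


# --- solver vs closed-form oracle ---------------------------------------


def _random_feasible_case(rng: np.random.Generator):
    """Random registry + medium with <= 8 items, feasible by construction."""
    n_items = int(rng.integers(1, 9))
    reg = StockRegistry()
    targets = {}
    fill = float(rng.choice([500, 1000, 2000]))
    budget = 0.95 * fill  # keep headroom so the well never overfills
    for i in range(n_items):
        unit = str(rng.choice(["g_per_L", "v_v_percent", "fold"]))
        comp = f"comp{i}"
        reg.add_component(Component(name=comp, unit_family=unit))
        stock_conc = float(rng.uniform(10, 500))
        reg.register_stock(StockSolution(f"stock{i}", {comp: stock_conc}))
        # ideal volume between min_transfer and an even share of the budget
        vol = float(rng.uniform(1.5, budget / n_items))
        targets[comp] = (vol / fill * stock_conc, unit)
    medium = MediumSpec(name="random", targets=targets, fill_volume_ul=fill)
    return reg, medium


def solver_oracle_study(n_media: int = 1000, seed: int = 0) -> dict:
    """Compare solver volumes with an independent dilution recomputation.

    For each random feasible medium the unrounded volume of every item is
    recomputed from first principles (C_target / C_stock * V_fill, summing
    split sub-steps back together) and compared to the solver's plan
    before-rounding equivalents; volume conservation is checked on every
    plan.  Returns the maximum absolute discrepancies in microliters.
    """
    rng = np.random.default_rng(seed)
    constraints = Constraints()
    max_oracle_err = 0.0
    max_conservation_err = 0.0
    for _ in range(n_media):
        reg, medium = _random_feasible_case(rng)
        plan = solve_blend(medium, reg, constraints)
        # independent oracle: closed form per item, no solver code
        stock_of = {}
        for item, (conc, _u) in medium.targets.items():
            stock = next(s for s in reg.stocks.values() if item in s.contents)
            stock_of[stock.name] = conc / stock.contents[item] * medium.fill_volume_ul
        dispensed = {}
        for src, vol in plan.steps:
            dispensed[src] = dispensed.get(src, 0.0) + vol
        for sname, ideal in stock_of.items():
            rounded_ideal = math.floor(ideal / constraints.resolution_ul + 0.5)
            rounded_ideal *= constraints.resolution_ul
            err = abs(dispensed.get(sname, 0.0) - rounded_ideal)
            max_oracle_err = max(max_oracle_err, err)
        total = sum(vol for _, vol in plan.steps)
        max_conservation_err = max(max_conservation_err, abs(total - medium.fill_volume_ul))
    return {
        "n_media": n_media,
        "max_oracle_error_ul": max_oracle_err,
        "max_conservation_error_ul": max_conservation_err,
    }


# --- quadratic recovery --------------------------------------------------


def quadratic_recovery_study() -> dict:
    """Noiseless in-model surfaces over classic factorial shapes.

    Shape A: a 3x2x3 factorial (two categorical factors, one numeric)
    with effect-coded categorical truth; shape B: a 3^4 numeric factorial
    with a natural-unit polynomial truth.  Both must be recovered to
    <1e-6 with exactly the generating terms retained.
    """
    # -- 3^4 numeric factorial, natural-unit truth
    design = full_factorial([
        ("ynb", [0.5, 1, 2]),
        ("fructose", [10, 30, 50]),
        ("urea", [1, 4, 7]),
        ("phosphate", [4, 10, 16]),
    ])
    df = design.to_dataframe().astype(float)
    truth = {"1": 2.0, "fructose": 0.09, "fructose^2": -0.002, "ynb*urea": 0.01}
    y = (
        truth["1"]
        + truth["fructose"] * df["fructose"]
        + truth["fructose^2"] * df["fructose"] ** 2
        + truth["ynb*urea"] * df["ynb"] * df["urea"]
    )
    model = fit_quadratic(df, y.to_numpy(), alpha=0.01)
    nat = model.natural_coefficients()
    err_numeric = max(
        abs(nat.get(k, 0.0) - v) for k, v in truth.items()
    )
    extra = {
        k for k, v in nat.items() if abs(v) > 1e-6 and k not in truth
    }
    terms_ok_numeric = not extra and {"fructose", "fructose^2", "ynb*urea"} <= set(
        t.name for t in model.terms
    )

    # -- 3x2x3 mixed factorial, truth built in the encoded space
    design2 = full_factorial([
        ("carbon", ["glycerol", "glucose", "fructose"]),
        ("nitrogen", ["urea", "ammonium_sulfate"]),
        ("pH", [5.0, 5.75, 6.5]),
    ])
    df2 = design2.to_dataframe()
    df2["pH"] = df2["pH"].astype(float)
    # effect coding used by the fitter: reference = first level
    def eff(col, levels):
        ref = levels[0]
        return [
            np.where(df2[col] == lv, 1.0, np.where(df2[col] == ref, -1.0, 0.0))
            for lv in levels[1:]
        ]
    c1, c2 = eff("carbon", ["glycerol", "glucose", "fructose"])
    (n1,) = eff("nitrogen", ["urea", "ammonium_sulfate"])
    z = (df2["pH"] - 5.75) / 0.75  # [-1, 1] coding
    gen = {  # coded-space generating coefficients
        "intercept": 1.0, "carbon[glucose]": 0.30, "carbon[fructose]": 0.35,
        "nitrogen[ammonium_sulfate]": -0.10, "nitrogen*pH": 0.20,
    }
    y2 = (
        gen["intercept"]
        + gen["carbon[glucose]"] * c1
        + gen["carbon[fructose]"] * c2
        + gen["nitrogen[ammonium_sulfate]"] * n1
        + gen["nitrogen*pH"] * n1 * z.to_numpy()
    )
    model2 = fit_quadratic(df2, y2, alpha=0.01)
    fitted = {}
    for t in model2.terms:
        for lbl, b in zip(t.column_labels, t.coefficients):
            fitted["intercept" if t.kind == "intercept" else
                   (t.name if t.kind != "linear" or t.factors[0] == "pH"
                    else lbl)] = float(b)
    # the nitrogen*pH interaction is single-column: label it by term name
    err_mixed = max(
        abs(fitted.get(k, 0.0) - v) for k, v in gen.items() if k != "intercept"
    )
    retained2 = {t.name for t in model2.terms if t.kind != "intercept"}
    terms_ok_mixed = retained2 == {"carbon", "nitrogen", "nitrogen*pH"}
    all_significant = all(
        t.adjusted_p <= 0.01 for m in (model, model2) for t in m.terms
        if t.kind != "intercept"
    )
    return {
        "max_coefficient_error": max(err_numeric, err_mixed),
        "retained_terms_correct": bool(terms_ok_numeric and terms_ok_mixed),
        "all_retained_significant": bool(all_significant),
        "r_squared": min(model.r_squared, model2.r_squared),
    }


# --- screen operating characteristics -----------------------------------


def _screen_once(truth: ResponseSurfaceTruth, n_supplements: int, prefix: str,
                 n_replicates: int, alpha: float, seed: int) -> set[str]:
    """One screening pass: names flagged beneficial."""
    base = MediumSpec(name="base", targets={}, fill_volume_ul=2000)
    media = [base] + [
        base.with_target(supplement_name(prefix, i), 1.0, "fold",
                         name=supplement_name(prefix, i))
        for i in range(n_supplements)
    ]
    data = {
        m.name: [r.value for r in evaluate(truth, m, n_replicates, replicate_seed=seed)]
        for m in media
    }
    screen = screen_vs_control(data, "base", alpha=alpha, adjust="bh", transform="log")
    return set(screen.labelled("beneficial"))


def screen_recovery_study(
    n_runs: int = 200,
    seed: int = 0,
    n_supplements: int = 16,
    n_beneficial: int = 5,
    effect: float = 1.5,
    noise_cv: float = 0.10,
    n_replicates: int = 3,
    alpha: float = 0.02,
) -> dict:
    """Sensitivity and false-positive behaviour of the supplement screen.

    Planted arm: how often >= (n_beneficial - 1) of the planted supplements
    are recovered.  Null arm: mean number of false flags when every
    supplement is inert.
    """
    prefix = "supplement"
    hits = 0
    for run in range(n_runs):
        truth = make_truth(
            TruthConfig(
                n_supplements=n_supplements, n_beneficial=n_beneficial,
                beneficial_effect=effect, screening_conc=1.0, noise_cv=noise_cv,
            ),
            seed=seed + run,
        )
        planted = {
            name for name, e in truth.component_effects.items() if e.shape == "boost"
        }
        found = _screen_once(truth, n_supplements, prefix, n_replicates, alpha,
                             seed=seed + run)
        if len(found & planted) >= n_beneficial - 1:
            hits += 1

    false_positives = 0
    for run in range(n_runs):
        truth = make_truth(
            TruthConfig(n_supplements=n_supplements, n_beneficial=0, noise_cv=noise_cv),
            seed=100_000 + seed + run,
        )
        found = _screen_once(truth, n_supplements, prefix, n_replicates, alpha,
                             seed=100_000 + seed + run)
        false_positives += len(found)

    return {
        "n_runs": n_runs,
        "recovery_rate": hits / n_runs,
        "mean_false_positives": false_positives / n_runs,
    }


# --- end-to-end optimizer recovery --------------------------------------


def planted_landscape(seed: int = 0, noise_cv: float = 0.05) -> tuple[
        ResponseSurfaceTruth, MediumSpec, list[LibraryEntry]]:
    """Landscape with two beneficial supplements (synergy 1.2) and a peaked
    base carbon source whose optimum lies inside the scanned range."""
    effects = {
        "fructose": ComponentEffect(shape="peaked", f_max=1.3, c_opt=22.5),
        "supp_A": boost_effect(1.0, 1.5),
        "supp_B": boost_effect(0.1, 1.5),
        "supp_C": ComponentEffect(shape="inert"),
        "supp_D": ComponentEffect(shape="inert"),
        "supp_E": ComponentEffect(shape="inhibitory", slope=2.0),
        "supp_F": ComponentEffect(shape="inert"),
    }
    truth = ResponseSurfaceTruth(
        baseline=1.0,
        component_effects=effects,
        interactions={frozenset({"supp_A", "supp_B"}): 1.2},
        noise_cv=noise_cv,
        seed=seed,
    )
    base = MediumSpec(
        name="base",
        targets={"fructose": (10.0, "g_per_L")},
        fill_volume_ul=2000,
    )
    library = [
        LibraryEntry("supp_A", "supp_A", 1.0, "fold", "amino_acid"),
        LibraryEntry("supp_B", "supp_B", 0.1, "v_v_percent", "trace_metal"),
        LibraryEntry("supp_C", "supp_C", 1.0, "fold", "vitamin"),
        LibraryEntry("supp_D", "supp_D", 1.0, "fold", "lipid"),
        LibraryEntry("supp_E", "supp_E", 0.5, "v_v_percent", "surfactant"),
        LibraryEntry("supp_F", "supp_F", 1.0, "fold", "other"),
    ]
    return truth, base, library


def optimizer_recovery_study(n_runs: int = 50, seed: int = 0) -> dict:
    """End-to-end greedy optimization on the planted landscape.

    Success: the final accepted medium's *noise-free* phenotype is at
    least 1.5x the base medium's.  Also verifies that the accepted mean is
    monotone non-decreasing in every audit log.
    """
    successes = 0
    monotone_all = True
    gains = []
    for run in range(n_runs):
        truth, base, library = planted_landscape(seed=seed + run, noise_cv=0.05)
        config = OptimizerConfig(
            n_replicates=3, alpha_screen=0.02, alpha_accept=0.05,
            max_rounds=3, tune_items=("fructose",),
            level_multipliers=(0.5, 1.0, 1.5, 2.25, 3.0),
            seed=seed + run,
        )
        state = optimize(base, library, SimulatorEvaluator(truth), config)
        gain = truth.true_mean(state.current_medium) / truth.true_mean(base)
        gains.append(gain)
        if gain >= 1.5:
            successes += 1
        accepted_means = _accepted_mean_trace(state)
        if any(b < a - 1e-9 for a, b in zip(accepted_means, accepted_means[1:])):
            monotone_all = False
    return {
        "n_runs": n_runs,
        "success_rate": successes / n_runs,
        "median_true_gain": float(np.median(gains)),
        "monotone_in_every_log": monotone_all,
    }


def _accepted_mean_trace(state) -> list[float]:
    """Best-mean trajectory implied by the audit log's accept decisions."""
    trace = []
    for rec in state.round_log:
        if rec.stage == "baseline":
            trace.append(float(np.mean(next(iter(rec.measurements.values())))))
        elif "accepted_mean" in rec.details:
            trace.append(float(rec.details["accepted_mean"]))
    return trace
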