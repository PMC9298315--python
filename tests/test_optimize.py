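import numpy as np
import pytest

from mediablend import (
    ComponentEffect,
    LibraryEntry,
    MediumSpec,
    OptimizerConfig,
    ResponseSurfaceTruth,
    SimulatorEvaluator,
    TableEvaluator,
    boost_effect,
    log_to_jsonl,
    optimize,
)
from mediablend.benchmarks import planted_landscape
from mediablend.optimize import (
    OptimizationState,
    read_library_csv,
    run_combination_stage,
    run_concentration_stage,
    run_supplement_stage,
)
from mediablend.simulate import measurements_to_frame, evaluate


def _state(medium, mean=1.0):
    return OptimizationState(current_medium=medium, best_mean=mean,
                             best_sd=0.0, best_n=3)


def noiseless_truth(extra_effects=None, interactions=None):
    effects = {
        "supp_A": boost_effect(1.0, 1.5),
        "supp_B": boost_effect(1.0, 1.4),
        "supp_C": ComponentEffect(shape="inert"),
        "supp_D": ComponentEffect(shape="inhibitory", slope=2.0),
    }
    effects.update(extra_effects or {})
    return ResponseSurfaceTruth(
        baseline=1.0, component_effects=effects,
        interactions=interactions or {}, noise_cv=0.0,
    )


LIBRARY = [
    LibraryEntry("supp_A", "supp_A", 1.0, "fold", "amino_acid"),
    LibraryEntry("supp_B", "supp_B", 1.0, "fold", "trace_metal"),
    LibraryEntry("supp_C", "supp_C", 1.0, "fold", "vitamin"),
    LibraryEntry("supp_D", "supp_D", 1.0, "fold", "surfactant"),
]

BASE = MediumSpec(name="base", targets={}, fill_volume_ul=2000)


class TestSupplementStage:
    def test_noiseless_screen_flags_planted_effects(self):
        state = _state(BASE)
        config = OptimizerConfig(n_replicates=3)
        beneficial = run_supplement_stage(
            state, LIBRARY, SimulatorEvaluator(noiseless_truth()), config, 1, seed=0)
        assert {e.supplement_name for e in beneficial} == {"supp_A", "supp_B"}
        assert "supp_D" in state.excluded  # detrimental removed from library
        assert state.round_log[-1].stage == "supplement_screen"

    def test_empty_library_sets_stop_reason(self):
        state = _state(BASE)
        out = run_supplement_stage(
            state, [], SimulatorEvaluator(noiseless_truth()), OptimizerConfig(), 1, 0)
        assert out == []
        assert state.stop_reason == "library_exhausted"

    def test_null_library_false_positive_rate(self):
        """All-inert supplements: flags are alpha-controlled across seeds."""
        inert = {f"supp_{c}": ComponentEffect(shape="inert") for c in "ABCD"}
        flags = 0
        for seed in range(40):
            truth = ResponseSurfaceTruth(baseline=1.0, component_effects=inert,
                                         noise_cv=0.10, seed=seed)
            state = _state(BASE)
            beneficial = run_supplement_stage(
                state, LIBRARY, SimulatorEvaluator(truth),
                OptimizerConfig(alpha_screen=0.02), 1, seed=seed)
            flags += len(beneficial) + len(state.excluded)
        assert flags / 40 <= 1.0


class TestCombinationStage:
    def test_counts_singles_plus_pairs(self):
        state = _state(BASE)
        truth = noiseless_truth()
        beneficial = [LIBRARY[0], LIBRARY[1], LIBRARY[2]]
        run_combination_stage(state, beneficial, SimulatorEvaluator(truth),
                              OptimizerConfig(), 1, seed=0)
        rec = state.round_log[-1]
        assert len(rec.candidates) == 3 + 3  # C(3,1) + C(3,2)

    def test_synergistic_pair_ranks_first_noiseless(self):
        truth = noiseless_truth(
            interactions={frozenset({"supp_A", "supp_B"}): 1.2})
        state = _state(BASE)
        chosen = run_combination_stage(
            state, [LIBRARY[0], LIBRARY[1]], SimulatorEvaluator(truth),
            OptimizerConfig(), 1, seed=0)
        assert {e.supplement_name for e in chosen} == {"supp_A", "supp_B"}
        # accepted medium contains both supplements at screening concentration
        assert state.current_medium.targets["supp_A"][0] == 1.0
        assert state.best_mean == pytest.approx(1.5 * 1.4 * 1.2)

    def test_single_candidate_trivially_chosen(self):
        state = _state(BASE)
        chosen = run_combination_stage(
            state, [LIBRARY[0]], SimulatorEvaluator(noiseless_truth()),
            OptimizerConfig(), 1, seed=0)
        assert [e.supplement_name for e in chosen] == ["supp_A"]


class TestConcentrationStage:
    def test_moves_to_grid_level_nearest_true_optimum(self):
        truth = noiseless_truth(
            extra_effects={"fructose": ComponentEffect(shape="peaked", f_max=1.3,
                                                       c_opt=22.5)})
        base = MediumSpec(name="m", targets={"fructose": (10.0, "g_per_L")},
                          fill_volume_ul=2000)
        state = _state(base, mean=truth.true_mean(base))
        config = OptimizerConfig(level_multipliers=(0.5, 1.0, 1.5, 2.25, 3.0))
        seeds = iter(range(100))
        changed = run_concentration_stage(
            state, ["fructose"], SimulatorEvaluator(truth), config, 1,
            lambda: next(seeds))
        assert changed
        assert state.current_medium.targets["fructose"][0] == pytest.approx(22.5)

    def test_flat_truth_keeps_incumbent(self):
        truth = noiseless_truth(
            extra_effects={"fructose": ComponentEffect(shape="inert")})
        base = MediumSpec(name="m", targets={"fructose": (10.0, "g_per_L")},
                          fill_volume_ul=2000)
        state = _state(base, mean=truth.true_mean(base))
        seeds = iter(range(100))
        changed = run_concentration_stage(
            state, ["fructose"], SimulatorEvaluator(truth), OptimizerConfig(), 1,
            lambda: next(seeds))
        assert not changed
        assert state.current_medium.targets["fructose"][0] == 10.0

    def test_lowest_level_wins_for_saturating_inhibition(self):
        """Minimum-effective-concentration behaviour: when the truth is
        best at the lowest tested dose, that dose is accepted."""
        truth = noiseless_truth(
            extra_effects={"ptm1": ComponentEffect(shape="inhibitory", slope=0.5)})
        base = MediumSpec(name="m", targets={"ptm1": (0.1, "v_v_percent")},
                          fill_volume_ul=2000)
        state = _state(base, mean=truth.true_mean(base))
        config = OptimizerConfig(level_multipliers=(0.25, 0.5, 1.0, 2.0))
        seeds = iter(range(100))
        changed = run_concentration_stage(
            state, ["ptm1"], SimulatorEvaluator(truth), config, 1,
            lambda: next(seeds))
        assert changed
        assert state.current_medium.targets["ptm1"][0] == pytest.approx(0.025)


class TestOptimize:
    def test_noiseless_full_loop_reaches_separable_optimum(self):
        truth, base, library = planted_landscape(seed=0, noise_cv=0.0)
        config = OptimizerConfig(
            tune_items=("fructose",),
            level_multipliers=(0.5, 1.0, 1.5, 2.25, 3.0), seed=0)
        state = optimize(base, library, SimulatorEvaluator(truth), config)
        assert state.current_medium.targets["fructose"][0] == pytest.approx(22.5)
        assert "supp_A" in state.current_medium.targets
        assert "supp_B" in state.current_medium.targets
        assert truth.true_mean(state.current_medium) >= 1.5 * truth.true_mean(base)

    def test_target_spec_below_base_stops_immediately(self):
        truth = noiseless_truth()
        state = optimize(BASE, LIBRARY, SimulatorEvaluator(truth),
                         OptimizerConfig(target_spec=0.5))
        assert state.stop_reason == "spec_met"
        assert len(state.round_log) == 1  # baseline only

    def test_empty_library_insensitive_truth_stops_no_gain(self):
        truth = noiseless_truth(
            extra_effects={"fructose": ComponentEffect(shape="inert")})
        base = MediumSpec(name="m", targets={"fructose": (10.0, "g_per_L")},
                          fill_volume_ul=2000)
        state = optimize(base, [], SimulatorEvaluator(truth),
                         OptimizerConfig(tune_items=("fructose",)))
        assert state.stop_reason == "no_gain"
        assert max(r.round_index for r in state.round_log) == 1

    def test_nothing_to_do_stops_library_exhausted(self):
        state = optimize(BASE, [], SimulatorEvaluator(noiseless_truth()),
                         OptimizerConfig())
        assert state.stop_reason == "library_exhausted"

    def test_best_mean_monotone_and_audit_complete(self):
        truth, base, library = planted_landscape(seed=5, noise_cv=0.05)
        config = OptimizerConfig(tune_items=("fructose",), seed=5)
        state = optimize(base, library, SimulatorEvaluator(truth), config)
        # every stage decision carries its measurements
        assert all(r.measurements or r.decision == "library empty"
                   for r in state.round_log)

    def test_rerun_reproduces_log_byte_for_byte(self):
        truth, base, library = planted_landscape(seed=2, noise_cv=0.05)
        config = OptimizerConfig(tune_items=("fructose",), seed=11)
        s1 = optimize(base, library, SimulatorEvaluator(truth), config)
        s2 = optimize(base, library, SimulatorEvaluator(truth), config)
        assert log_to_jsonl(s1) == log_to_jsonl(s2)


class TestAdapters:
    def test_table_evaluator_round_trip(self):
        truth = noiseless_truth()
        m = MediumSpec(name="base+supp_A", targets={"supp_A": (1.0, "fold")},
                       fill_volume_ul=2000)
        frame = measurements_to_frame(evaluate(truth, m, 3))
        ev = TableEvaluator(frame)
        assert ev.measure([m], 3, seed=0)[m.name] == [1.5, 1.5, 1.5]

    def test_library_csv(self, tmp_path):
        path = tmp_path / "library.csv"
        path.write_text(
            "supplement_name,stock_name,screening_concentration,unit,category\n"
            "MEM AA,MEM AA 50x,1,fold,amino_acid\n"
            "PTM1,PTM1 10%,0.1,v_v_percent,trace_metal\n"
        )
        lib = read_library_csv(path)
        assert lib[0] == LibraryEntry("MEM AA", "MEM AA 50x", 1.0, "fold", "amino_acid")
        assert lib[1].screening_concentration == 0.1
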