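import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mediablend import (
    MediumSpec,
    fit_quadratic,
    full_factorial,
    ofaat_design,
    optimum_on_surface,
    rank_effects,
    ratio_grid,
    screen_vs_control,
    welch_one_tailed,
)
from mediablend.doe import welch_statistic
from mediablend.errors import (
    EmptyFactor,
    MissingControl,
    TooFewReplicates,
    TooFewRuns,
)


class TestFullFactorial:
    def test_carbon_nitrogen_ph_is_18_runs(self):
        design = full_factorial([
            ("carbon", ["glycerol", "glucose", "fructose"]),
            ("nitrogen", ["urea", "ammonium_sulfate"]),
            ("pH", [5, 5.75, 6.5]),
        ])
        assert len(design) == 18

    def test_enumeration_order(self):
        design = full_factorial([("A", [1, 2]), ("B", ["x", "y"])])
        assert design.runs == [(1, "x"), (1, "y"), (2, "x"), (2, "y")]

    def test_3_to_the_4_concentration_factorial(self):
        design = full_factorial([
            ("ynb", [0.5, 1, 2]),
            ("fructose", [10, 30, 50]),
            ("urea", [1, 4, 7]),
            ("phosphate", [4, 10, 16]),
        ])
        assert len(design) == 81

    def test_empty_factor_rejected(self):
        with pytest.raises(EmptyFactor):
            full_factorial([])
        with pytest.raises(EmptyFactor):
            full_factorial([("A", [1])])

    @settings(deadline=None, max_examples=50)
    @given(
        level_counts=st.lists(st.integers(2, 5), min_size=1, max_size=4)
    )
    def test_size_is_product_of_levels(self, level_counts):
        factors = [(f"f{i}", list(range(n))) for i, n in enumerate(level_counts)]
        assert len(full_factorial(factors)) == int(np.prod(level_counts))


class TestOfaatAndRatioGrid:
    def test_ofaat_varies_only_the_factor(self, dm1_base):
        levels = [5.6, 11.25, 22.5, 45.0]  # 8-fold range
        media = ofaat_design(dm1_base, "fructose", levels)
        assert len(media) == 4
        for m, level in zip(media, levels):
            assert m.targets["fructose"][0] == level
            rest = {k: v for k, v in m.targets.items() if k != "fructose"}
            base_rest = {k: v for k, v in dm1_base.targets.items() if k != "fructose"}
            assert rest == base_rest

    def test_level_zero_removes_supplement(self, dm1_base):
        (m,) = ofaat_design(dm1_base, "fructose", [0])
        assert "fructose" not in m.targets

    def test_level_equal_to_base_is_identity(self, dm1_base):
        (m,) = ofaat_design(dm1_base, "fructose", [22.5])
        assert m.targets == dm1_base.targets

    @pytest.mark.parametrize(
        "ratio,total,expected",
        [((1, 1), 20, (10, 10)), ((3, 1), 40, (30, 10)), ((1, 3), 70, (17.5, 52.5))],
    )
    def test_ratio_grid_split(self, ratio, total, expected):
        (row,) = ratio_grid(("sorbitol", "methanol"), [ratio], [total])
        assert (row["sorbitol"], row["methanol"]) == pytest.approx(expected)

    def test_ratio_grid_pure_controls(self):
        rows = ratio_grid(("sorbitol", "methanol"), [(1, 1)], [20], include_pure=True)
        assert len(rows) == 3
        pures = [r for r in rows if r["ratio"].startswith("pure")]
        assert {(r["sorbitol"], r["methanol"]) for r in pures} == {(20, 0.0), (0.0, 20)}


class TestFitQuadratic:
    def test_noiseless_parabola_recovered(self):
        """y = 2 + 3a - a^2 on a 5-level grid, exact recovery."""
        a = np.repeat(np.linspace(0, 4, 5), 2)
        df = pd.DataFrame({"a": a})
        y = 2 + 3 * a - a**2
        model = fit_quadratic(df, y, alpha=0.01)
        nat = model.natural_coefficients()
        assert nat["1"] == pytest.approx(2, abs=1e-6)
        assert nat["a"] == pytest.approx(3, abs=1e-6)
        assert nat["a^2"] == pytest.approx(-1, abs=1e-6)
        assert {t.name for t in model.terms} == {"intercept", "a", "a^2"}
        assert model.r_squared == pytest.approx(1.0)

    def test_constant_response_gives_intercept_only(self):
        df = pd.DataFrame({"a": [0, 1, 2, 0, 1, 2, 0, 1, 2]})
        model = fit_quadratic(df, np.full(9, 5.0), alpha=0.01)
        assert model.term_names == ["intercept"]
        assert model.r_squared == 0.0

    def test_pure_interaction_retained_linear_dropped(self):
        """Noiseless y = a*b on a replicated 2x2: the interaction term
        survives elimination while the exactly-zero linear terms go."""
        runs = list(itertools.product([-1, 1], [-1, 1])) * 3
        df = pd.DataFrame(runs, columns=["a", "b"])
        y = df["a"] * df["b"]
        model = fit_quadratic(df, y.to_numpy(), alpha=0.01)
        retained = {t.name for t in model.terms if t.kind != "intercept"}
        assert retained == {"a*b"}
        assert model.term("a*b").coefficient == pytest.approx(1.0, abs=1e-9)

    def test_log_transform(self):
        a = np.repeat(np.linspace(1, 3, 5), 3)
        df = pd.DataFrame({"a": a})
        y = np.exp(1.0 + 0.5 * a)
        model = fit_quadratic(df, y, transform="log", alpha=0.01)
        nat = model.natural_coefficients()
        assert nat["a"] == pytest.approx(0.5, abs=1e-6)

    def test_too_few_runs(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(TooFewRuns):
            fit_quadratic(df, np.array([1.0, 2.0, 3.0]))

    def test_elimination_keeps_all_terms_significant(self):
        """With noise, every retained term passes alpha and the loop
        terminates within the candidate-term count."""
        rng = np.random.default_rng(7)
        design = full_factorial([("a", [-1, 0, 1]), ("b", [-1, 0, 1])])
        df = pd.concat([design.to_dataframe().astype(float)] * 4, ignore_index=True)
        y = 1 + 2 * df["a"] + rng.normal(0, 0.3, len(df))
        model = fit_quadratic(df, y.to_numpy(), alpha=0.01)
        for t in model.terms:
            if t.kind != "intercept":
                assert t.adjusted_p <= 0.01
        assert len(model.elimination_log) <= 6

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(3)
        design = full_factorial([("a", [-1, 0, 1]), ("b", [-1, 0, 1])])
        df = pd.concat([design.to_dataframe().astype(float)] * 3, ignore_index=True)
        y = 1 + df["a"] + rng.normal(0, 0.5, len(df))
        model = fit_quadratic(df, y.to_numpy(), alpha=0.9, adjust="bh")
        for t in model.terms:
            if t.kind != "intercept" and not np.isnan(t.raw_p):
                assert t.adjusted_p >= t.raw_p - 1e-12


class TestRankEffects:
    def test_sorted_by_adjusted_p_then_coef(self):
        df = pd.DataFrame({"a": [-1.0, 0, 1] * 6, "b": [-1.0, -1, -1, 1, 1, 1] * 3})
        rng = np.random.default_rng(0)
        y = 1 + 3 * df["a"] + 0.5 * df["b"] + rng.normal(0, 0.2, len(df))
        model = fit_quadratic(df, y.to_numpy(), alpha=0.05)
        ranked = rank_effects(model)
        assert all(t.kind != "intercept" for t in ranked)
        ps = [t.adjusted_p for t in ranked]
        assert ps == sorted(ps)
        assert ranked[0].name == "a"


class TestOptimumOnSurface:
    def _fit(self, a, y):
        return fit_quadratic(pd.DataFrame({"a": a}), y, alpha=0.05)

    def test_interior_vertex(self):
        a = np.repeat(np.linspace(0, 1, 5), 2)
        model = self._fit(a, -((a - 0.5) ** 2))
        loc, _val, boundary = optimum_on_surface(model, {"a": (0.0, 1.0)})
        assert loc["a"] == pytest.approx(0.5, abs=1e-9)
        assert not boundary

    def test_monotone_is_boundary_flagged(self):
        a = np.repeat(np.linspace(0, 1, 5), 2)
        model = self._fit(a, a.copy())
        loc, _val, boundary = optimum_on_surface(model, {"a": (0.0, 1.0)})
        assert loc["a"] == pytest.approx(1.0)
        assert boundary

    def test_vertex_formula(self):
        a = np.repeat(np.linspace(0, 4, 9), 2)
        model = self._fit(a, 2 + 3 * a - a**2)
        loc, val, _ = optimum_on_surface(model, {"a": (0.0, 4.0)})
        assert loc["a"] == pytest.approx(1.5, abs=1e-9)
        assert val == pytest.approx(2 + 3 * 1.5 - 1.5**2, abs=1e-6)

    def test_two_factor_surface(self):
        design = full_factorial([("a", [0, 0.5, 1.0]), ("b", [0, 0.5, 1.0])])
        df = design.to_dataframe().astype(float)
        y = -((df["a"] - 0.25) ** 2) - (df["b"] - 0.75) ** 2
        model = fit_quadratic(df, y.to_numpy(), alpha=0.05)
        loc, _val, _ = optimum_on_surface(model, {"a": (0, 1), "b": (0, 1)}, grid_points=201)
        assert loc["a"] == pytest.approx(0.25, abs=0.01)
        assert loc["b"] == pytest.approx(0.75, abs=0.01)


class TestScreenVsControl:
    def test_beneficial_and_detrimental_oracle(self):
        """Hand-checked contrasts: +50% is beneficial, -50% detrimental."""
        data = {
            "CTRL": [1.00, 1.02, 0.98],
            "up": [1.50, 1.52, 1.48],
            "down": [0.50, 0.51, 0.49],
        }
        result = screen_vs_control(data, "CTRL", alpha=0.02)
        assert result.effects["up"].direction == "beneficial"
        assert result.effects["down"].direction == "detrimental"
        assert result.effects["up"].mean_ratio == pytest.approx(1.5)
        # independent pooled-t oracle for the 'up' contrast in a 3-group frame
        groups = [np.array(v) for v in data.values()]
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (9 - 3)
        t = (np.mean(data["up"]) - np.mean(data["CTRL"])) / np.sqrt(mse * (2 / 3))
        p = 2 * stats.t.sf(abs(t), 6)
        assert result.effects["up"].raw_p == pytest.approx(p)

    def test_identical_condition_is_null(self):
        data = {"CTRL": [1.00, 1.02, 0.98], "same": [1.00, 1.02, 0.98]}
        result = screen_vs_control(data, "CTRL", alpha=0.02)
        assert result.effects["same"].direction == "null"
        assert result.effects["same"].adjusted_p == pytest.approx(1.0)

    def test_missing_control_and_too_few_replicates(self):
        with pytest.raises(MissingControl):
            screen_vs_control({"a": [1, 2]}, "CTRL")
        with pytest.raises(TooFewReplicates):
            screen_vs_control({"CTRL": [1.0], "a": [1, 2]}, "CTRL")

    def test_adjustment_monotone(self):
        rng = np.random.default_rng(5)
        data = {"CTRL": list(rng.normal(1, 0.05, 3))}
        for i in range(8):
            data[f"c{i}"] = list(rng.normal(1 + 0.05 * i, 0.05, 3))
        result = screen_vs_control(data, "CTRL", alpha=0.02, adjust="bh")
        for e in result.effects.values():
            assert e.adjusted_p >= e.raw_p - 1e-12


class TestWelchOneTailed:
    def test_hand_computed_example(self):
        a, b = [10, 11, 12], [13, 14, 15]
        t, df = welch_statistic(a, b)
        assert t == pytest.approx(3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        p = welch_one_tailed(a, b, alternative="b_greater")
        # oracle: t-distribution tail at the hand-computed statistic
        assert p == pytest.approx(stats.t.sf(3.6742346, 4), abs=1e-4)
        assert p == pytest.approx(0.0107, abs=5e-4)

    def test_identical_samples_give_half(self):
        assert welch_one_tailed([10, 11, 12], [10, 11, 12]) == pytest.approx(0.5)

    def test_directions_are_complementary(self):
        a, b = [10, 11, 12], [13, 14, 15]
        p1 = welch_one_tailed(a, b, alternative="b_greater")
        p2 = welch_one_tailed(a, b, alternative="a_greater")
        assert p1 + p2 == pytest.approx(1.0)
        assert p2 == pytest.approx(0.9893, abs=5e-4)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.lists(st.floats(-100, 100), min_size=2, max_size=6),
        b=st.lists(st.floats(-100, 100), min_size=2, max_size=6),
    )
    def test_complementarity_property(self, a, b):
        p1 = welch_one_tailed(a, b, alternative="b_greater")
        p2 = welch_one_tailed(a, b, alternative="a_greater")
        assert p1 + p2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_degenerate(self):
        assert welch_one_tailed([1, 1], [2, 2], alternative="b_greater") == 0.0
        assert welch_one_tailed([1, 1], [2, 2], alternative="a_greater") == 1.0
        assert welch_one_tailed([1, 1], [1, 1]) == 0.5

    def test_too_few_replicates(self):
        with pytest.raises(TooFewReplicates):
            welch_one_tailed([1.0], [1, 2])
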