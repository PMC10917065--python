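"""Positivity thresholds, calls, reactivity categories, antigen ratios,
forest statistics and group comparisons."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seromic import (
    PositivityModel,
    antigen_ratio,
    call_positivity,
    categorize_reactivity,
    compare_groups,
    compute_thresholds,
    isotype_positive_proportion,
    reactivity_table,
    subclass_forest,
)
from seromic.positivity import CATEGORY_SYMBOLS, significance_stars


def _df(rows, samples=None, antigens=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    antigens = antigens or [f"A{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=samples, columns=antigens)


class TestThresholds:
    def test_mean_plus_two_sd(self):
        v = _df([[10], [12], [14]])
        thr = compute_thresholds(v, v.index)
        assert thr.table.loc["A0", "mean"] == 12
        assert thr.table.loc["A0", "sd"] == pytest.approx(2.0)
        assert thr.table.loc["A0", "threshold"] == pytest.approx(16.0)
        assert not thr.table.loc["A0", "degenerate"]

    def test_zero_variance_flagged_degenerate(self):
        v = _df([[5], [5], [5]])
        thr = compute_thresholds(v, v.index)
        assert thr.table.loc["A0", "threshold"] == 5
        assert bool(thr.table.loc["A0", "degenerate"])

    def test_insufficient_controls_excludes_antigen(self):
        v = _df([[1, 1], [2, np.nan], [3, np.nan]])
        thr = compute_thresholds(v, v.index)
        assert "A0" in thr.table.index and "A1" not in thr.table.index

    def test_large_n_standard_normal_converges_to_two(self):
        rng = np.random.default_rng(1)
        v = _df(rng.normal(0, 1, size=(5000, 3)))
        thr = compute_thresholds(v, v.index)
        np.testing.assert_allclose(thr.threshold, 2.0, atol=0.1)


class TestCalls:
    def test_boundary_equality_is_negative(self):
        ctrl = _df([[10], [12], [14]])
        thr = compute_thresholds(ctrl, ctrl.index)
        test = _df([[16.0], [16.0000001]], samples=["T1", "T2"])
        calls = call_positivity(test, thr).calls
        assert not calls.loc["T1", "A0"]
        assert calls.loc["T2", "A0"]

    def test_missing_rfu_gives_missing_call(self):
        ctrl = _df([[10], [12], [14]])
        thr = compute_thresholds(ctrl, ctrl.index)
        test = _df([[np.nan]], samples=["T1"])
        calls = call_positivity(test, thr).calls
        assert pd.isna(calls.loc["T1", "A0"])

    def test_raising_one_value_never_lowers_positive_count(self):
        rng = np.random.default_rng(2)
        ctrl = _df(rng.normal(100, 10, size=(10, 6)))
        thr = compute_thresholds(ctrl, ctrl.index)
        test = _df(rng.normal(100, 10, size=(4, 6)), samples=list("WXYZ"))
        base = call_positivity(test, thr).positive_count
        for s in test.index:
            for a in test.columns:
                bumped = test.copy()
                bumped.loc[s, a] += 50
                new = call_positivity(bumped, thr).positive_count
                assert new[s] >= base[s]

    def test_threshold_shift_equivariance(self):
        """Adding a constant to all control and test values shifts the
        thresholds by that constant and leaves every call unchanged."""
        rng = np.random.default_rng(3)
        ctrl = _df(rng.normal(50, 5, size=(8, 5)))
        test = _df(rng.normal(50, 5, size=(6, 5)), samples=[f"T{i}" for i in range(6)])
        c = 123.456
        thr0 = compute_thresholds(ctrl, ctrl.index)
        thr1 = compute_thresholds(ctrl + c, ctrl.index)
        np.testing.assert_allclose(thr1.threshold, thr0.threshold + c, rtol=1e-12)
        assert call_positivity(test, thr0).calls.equals(
            call_positivity(test + c, thr1).calls)


class TestCategories:
    @pytest.mark.parametrize("count,expected", [
        (0, "absent"), (1, "weak"), (29, "weak"), (30, "moderate"), (47, "moderate"),
        (48, "strong"), (63, "strong"), (64, "very_strong"), (80, "very_strong"),
        (81, "PSA"), (200, "PSA"),
    ])
    def test_symbol_key_boundaries(self, count, expected):
        assert categorize_reactivity(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            categorize_reactivity(-1)

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=200, derandomize=True)
    def test_bins_exhaustive_and_exclusive(self, count):
        cat = categorize_reactivity(count)
        assert cat in CATEGORY_SYMBOLS
        # boundaries are contiguous: adjacent counts map to the same or the
        # immediately following category
        order = ["absent", "weak", "moderate", "strong", "very_strong", "PSA"]
        nxt = categorize_reactivity(count + 1)
        assert 0 <= order.index(nxt) - order.index(cat) <= 1


class TestAntigenRatio:
    def test_worked_ratio(self):
        calls = pd.Series([True] * 60 + [False] * 202)
        assert antigen_ratio(calls) == pytest.approx(60 / 202, abs=1e-10)
        assert antigen_ratio(calls) == pytest.approx(0.29703, abs=1e-5)

    def test_no_positives_gives_zero(self):
        assert antigen_ratio(pd.Series([False] * 10)) == 0.0

    def test_all_positive_flagged_infinite(self):
        assert np.isinf(antigen_ratio(pd.Series([True] * 10)))


class TestSubclassForest:
    def test_identical_ratios_give_exact_zero(self):
        r = pd.Series([0.1, 0.4, 0.2, 0.6], index=list("abcd"))
        stat = subclass_forest(r, r)
        assert stat.mean_difference == 0.0
        assert stat.ci_low <= 0.0 <= stat.ci_high

    def test_constant_difference_zero_width_ci(self):
        iso = pd.Series([0.5, 0.7, 0.9], index=list("abc"))
        stat = subclass_forest(iso, iso - 0.2)
        assert stat.mean_difference == pytest.approx(0.2)
        assert stat.ci_low == pytest.approx(0.2) and stat.ci_high == pytest.approx(0.2)

    def test_dominant_subclass_more_negative_than_rare(self):
        rng = np.random.default_rng(4)
        idx = [f"S{i}" for i in range(20)]
        iso = pd.Series(rng.uniform(0.3, 0.5, 20), index=idx)
        dominant = iso * rng.uniform(0.95, 1.0, 20)   # carries almost all binding
        rare = iso * rng.uniform(0.05, 0.15, 20)
        d = subclass_forest(iso, dominant)
        r = subclass_forest(iso, rare)
        assert d.mean_difference < r.mean_difference

    def test_infinite_ratios_excluded_and_small_n_rejected(self):
        iso = pd.Series([np.inf, 0.2, 0.3], index=list("abc"))
        stat = subclass_forest(iso, iso * 0.5)
        assert stat.n == 2
        with pytest.raises(ValueError):
            subclass_forest(pd.Series([np.inf, 1.0], index=list("ab")),
                            pd.Series([1.0, np.inf], index=list("ab")))

    def test_bootstrap_interval_brackets_mean(self):
        rng = np.random.default_rng(5)
        iso = pd.Series(rng.uniform(0.2, 0.8, 30))
        sub = iso - rng.normal(0.1, 0.02, 30)
        stat = subclass_forest(iso, sub, method="bootstrap", seed=1)
        assert stat.ci_low <= stat.mean_difference <= stat.ci_high


class TestCompareGroups:
    def test_identical_groups_no_signal(self):
        vals = pd.Series(list(range(10)) * 2, dtype=float)
        groups = pd.Series(["A"] * 10 + ["B"] * 10)
        res = compare_groups(vals, groups, control_group="A")
        assert res.anova_f == pytest.approx(0.0, abs=1e-12)
        assert res.anova_p == pytest.approx(1.0)
        assert res.pairwise.iloc[0]["stars"] == "ns"

    def test_five_sd_shift_is_four_stars(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        vals = pd.Series(np.concatenate([a, b]))
        groups = pd.Series(["ctrl"] * 30 + ["case"] * 30)
        res = compare_groups(vals, groups, control_group="ctrl")
        row = res.pairwise.set_index("group").loc["case"]
        assert row["p_adj"] < 1e-4 and row["stars"] == "****"

    def test_anova_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        data = {g: rng.normal(m, 1.3, n)
                for g, m, n in [("A", 0, 8), ("B", 0.8, 11), ("C", -0.4, 9)]}
        vals = pd.Series(np.concatenate(list(data.values())))
        groups = pd.Series(sum(([g] * len(v) for g, v in data.items()), []))
        res = compare_groups(vals, groups, control_group="A")
        # brute-force one-way ANOVA F from sums of squares
        grand = vals.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
        k, n = len(data), len(vals)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.anova_f == pytest.approx(f_oracle, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(pd.Series([1.0, 2.0]), pd.Series(["A", "A"]), "A")

    @pytest.mark.parametrize("p,stars", [(0.04, "*"), (0.009, "**"), (0.0009, "***"),
                                         (0.00009, "****"), (0.06, "ns")])
    def test_star_mapping(self, p, stars):
        assert significance_stars(p) == stars


class TestIsotypeProportion:
    def _calls(self, rows, samples):
        return pd.DataFrame(np.asarray(rows, dtype=bool), index=samples,
                            columns=[f"A{j}" for j in range(len(rows[0]))]).astype("boolean")

    def test_identical_matrices_null(self):
        samples = [f"S{i}" for i in range(6)]
        calls = self._calls(np.eye(6, 8), samples)
        groups = pd.Series(["G1"] * 6, index=samples)
        out = isotype_positive_proportion(calls, calls, groups)
        assert out.iloc[0]["mean_diff_IgA_minus_IgG"] == 0.0
        assert out.iloc[0]["p_raw"] == 1.0

    def test_planted_group_specific_excess_detected(self):
        rng = np.random.default_rng(8)
        samples = [f"S{i}" for i in range(40)]
        igg = self._calls(rng.random((40, 50)) < 0.05, samples)
        iga_rows = rng.random((40, 50)) < 0.05
        iga_rows[:20] = rng.random((20, 50)) < 0.3   # planted excess in group G1
        iga = self._calls(iga_rows, samples)
        groups = pd.Series(["G1"] * 20 + ["G2"] * 20, index=samples)
        out = isotype_positive_proportion(igg, iga, groups).set_index("group")
        assert out.loc["G1", "p_adj"] < 0.01
        assert out.loc["G2", "p_adj"] > 0.05

    def test_disjoint_samples_rejected(self):
        a = self._calls([[1, 0]], ["S1"])
        b = self._calls([[1, 0]], ["S2"])
        with pytest.raises(ValueError):
            isotype_positive_proportion(a, b, pd.Series({"S1": "G"}))


class TestModelSurface:
    def test_fit_summary_and_reactivity_grid(self, small_rfu, small_cohort):
        res = PositivityModel(small_rfu["IgG"], small_cohort, "LTBI").fit()
        summ = res.summary()
        assert {"group", "positive_count", "category", "symbol",
                "antigen_ratio"} <= set(summ.columns)
        assert (summ["positive_count"] + res.calls.negative_count
                == res.calls.calls.notna().sum(axis=1)).all()
        grid = reactivity_table({"IgG": res})
        assert set(grid["IgG"]) <= set(CATEGORY_SYMBOLS.values())

    def test_unknown_control_group_rejected(self, small_rfu, small_cohort):
        with pytest.raises(ValueError):
            PositivityModel(small_rfu["IgG"], small_cohort, "NOPE")
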