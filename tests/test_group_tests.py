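"""One-way ANOVA, Tukey HSD letter display and MANOVA against independent
oracles (nested-model residual sums of squares, scipy's studentized-range
implementation, null-simulation uniformity)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qtgtest import manova, one_way_anova, significance_summary, tukey_hsd


def anova_f_oracle(values, groups):
    """F from explicit nested-model RSS: cell-means model vs grand mean."""
    values = np.asarray(values, float)
    labels = np.unique(groups)
    X_full = np.column_stack([(groups == g).astype(float) for g in labels])
    beta, *_ = np.linalg.lstsq(X_full, values, rcond=None)
    rss_full = np.sum((values - X_full @ beta) ** 2)
    rss_null = np.sum((values - values.mean()) ** 2)
    df1, df2 = len(labels) - 1, len(values) - len(labels)
    return ((rss_null - rss_full) / df1) / (rss_full / df2)


class TestOneWayAnova:
    def test_two_groups_f_equals_squared_t(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.5, 1.0, size=15)
        res = one_way_anova(np.r_[a, b], np.r_[["a"] * 12, ["b"] * 15])
        t, p = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t ** 2, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_identical_groups_give_f_zero_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        grp = np.repeat(["a", "b", "c"], 3)
        vals = np.concatenate([[1., 2., 3.]] * 3)
        res = one_way_anova(vals, grp)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_all_constant_values_give_f_zero_p_one(self):
        res = one_way_anova(np.ones(9), np.repeat(["a", "b", "c"], 3))
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_nested_rss_oracle_on_random_instances(self, rng):
        for _ in range(20):
            groups = np.repeat(["a", "b", "c"], 10)
            values = rng.normal(size=30) + rng.normal(size=3)[
                np.searchsorted(["a", "b", "c"], groups)]
            res = one_way_anova(values, groups)
            assert res.f_statistic == pytest.approx(
                anova_f_oracle(values, groups), abs=1e-9)

    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None)
    def test_f_invariant_to_affine_transform(self, shift, scale):
        rng = np.random.default_rng(42)
        values = rng.normal(size=24)
        groups = np.repeat(["a", "b", "c"], 8)
        f0 = one_way_anova(values, groups).f_statistic
        f1 = one_way_anova(values * scale + shift, groups).f_statistic
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_rejects_single_group_or_singleton(self):
        with pytest.raises(ValueError, match="two groups"):
            one_way_anova([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ValueError, match="two observations"):
            one_way_anova([1, 2, 3], ["a", "a", "b"])


class TestTukeyHsd:
    def test_pairwise_p_matches_scipy_oracle(self, rng):
        for _ in range(10):
            samples = [rng.normal(m, 1.0, size=n)
                       for m, n in [(0, 8), (0.7, 12), (1.5, 9)]]
            values = np.concatenate(samples)
            groups = np.r_[["a"] * 8, ["b"] * 12, ["c"] * 9]
            res = tukey_hsd(values, groups)
            oracle = stats.tukey_hsd(*samples)
            mine = {tuple(sorted((r.group1, r.group2))): r.p_value
                    for r in res.pairwise.itertuples()}
            for (i, gi), (j, gj) in [((0, "a"), (1, "b")),
                                     ((0, "a"), (2, "c")),
                                     ((1, "b"), (2, "c"))]:
                assert mine[(gi, gj)] == pytest.approx(
                    oracle.pvalue[i, j], abs=1e-4)

    def test_extremely_shifted_group_gets_unique_letter(self, rng):
        values = np.r_[rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                       rng.normal(100, 1, 10)]
        groups = np.repeat(["a", "b", "far"], 10)
        res = tukey_hsd(values, groups)
        assert set(res.letters["far"]).isdisjoint(res.letters["a"])
        assert set(res.letters["far"]).isdisjoint(res.letters["b"])

    def test_null_groups_share_one_letter_most_of_the_time(self):
        shared = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(4000 + i)
            values = rng.normal(size=90)
            groups = np.repeat(["a", "b", "c"], 30)
            res = tukey_hsd(values, groups)
            shared += len(set(res.letters.values())) == 1
        assert shared >= 0.9 * reps

    def test_letter_display_is_consistent_with_pairwise_matrix(self, rng):
        # draw means close enough to produce mixed significance patterns
        for i in range(10):
            r = np.random.default_rng(5000 + i)
            values = np.concatenate([r.normal(m, 1.0, 12)
                                     for m in (0.0, 0.8, 1.6, 2.4)])
            groups = np.repeat(list("abcd"), 12)
            res = tukey_hsd(values, groups)
            for row in res.pairwise.itertuples():
                share = bool(set(res.letters[row.group1])
                             & set(res.letters[row.group2]))
                assert share == (row.p_value >= res.alpha)
            assert all(res.letters[g] for g in "abcd")

    def test_two_groups_degenerate_to_single_comparison(self, rng):
        values = np.r_[rng.normal(size=8), rng.normal(2, 1, size=8)]
        res = tukey_hsd(values, np.repeat(["a", "b"], 8))
        assert len(res.pairwise) == 1


class TestManova:
    def test_single_response_reduces_to_anova(self, rng):
        values = rng.normal(size=36)
        groups = np.repeat(["a", "b", "c"], 12)
        aov = one_way_anova(values, groups)
        df = pd.DataFrame({"y": values, "g": groups})
        res = manova(df[["y"]], df[["g"]], "C(g)")
        tab = res.tables["C(g)"]
        assert np.allclose(tab["p_value"], aov.p_value, atol=1e-8)
        assert np.allclose(tab["f_value"], aov.f_statistic, atol=1e-8)

    def test_null_wilks_p_uniform_by_ks(self):
        pvals = []
        for i in range(300):
            rng = np.random.default_rng(6000 + i)
            df = pd.DataFrame({"y1": rng.normal(size=60),
                               "y2": rng.normal(size=60),
                               "g": np.repeat(["a", "b", "c"], 20)})
            res = manova(df[["y1", "y2"]], df[["g"]], "C(g)")
            pvals.append(res.tables["C(g)"].loc["wilks_lambda", "p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_four_statistics_reported_with_valid_ranges(self, rng):
        df = pd.DataFrame({"y1": rng.normal(size=60),
                           "y2": rng.normal(size=60),
                           "y3": rng.normal(size=60),
                           "g": np.repeat(["a", "b", "c"], 20),
                           "s": np.tile(["M", "F"], 30)})
        res = manova(df[["y1", "y2", "y3"]], df[["g", "s"]], "C(g) * C(s)")
        for term, tab in res.tables.items():
            assert set(tab.index) == {"wilks_lambda", "pillai_trace",
                                      "hotelling_lawley", "roys_root"}
            assert tab["p_value"].between(0, 1).all()
        assert 0 < tab.loc["wilks_lambda", "value"] <= 1

    def test_collinear_responses_named_in_error(self, rng):
        y = rng.normal(size=30)
        df = pd.DataFrame({"y1": y, "y2": 2 * y + 1,
                           "g": np.repeat(["a", "b", "c"], 10)})
        with pytest.raises(ValueError, match="y1~y2"):
            manova(df[["y1", "y2"]], df[["g"]], "C(g)")

    def test_too_few_cases_rejected(self, rng):
        df = pd.DataFrame({f"y{i}": rng.normal(size=5) for i in range(5)}
                          | {"g": ["a", "a", "b", "b", "b"]})
        with pytest.raises(ValueError, match="complete cases"):
            manova(df[[f"y{i}" for i in range(5)]], df[["g"]], "C(g)")


class TestSignificanceSummary:
    def _result_with(self, pvals):
        from qtgtest.group_tests import ManovaResult
        tab = pd.DataFrame({
            "statistic": ["wilks_lambda", "pillai_trace",
                          "hotelling_lawley", "roys_root"],
            "value": 0.5, "f_value": 1.0, "df_num": 2.0, "df_den": 10.0,
            "p_value": pvals}).set_index("statistic")
        return ManovaResult({"term": tab}, n=20, responses=("y",))

    def test_all_significant_sets_both_flags(self):
        flags = significance_summary(self._result_with([0.01] * 4))
        assert flags.loc["term"].all()

    def test_only_roy_significant_sets_any_not_all(self):
        flags = significance_summary(
            self._result_with([0.2, 0.3, 0.15, 0.01]))
        assert flags.loc["term", "significant_any_statistic"]
        assert not flags.loc["term", "significant_all_statistics"]

    def test_none_significant_clears_both(self):
        flags = significance_summary(self._result_with([0.2, 0.3, 0.4, 0.5]))
        assert not flags.loc["term"].any()
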