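import numpy as np
import pandas as pd
import pytest

from chronofeed.stats import (
    GroupSummary,
    distribution_screens,
    holm_sidak,
    observed_power_t,
    pearson,
    t_from_summary,
    t_two_sample,
    two_way_rm_anova,
)


class TestSummaryT:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected_t",
        [
            (32.1, 2.2, 43.4, 2.9, -3.105),  # rhythm power
            (27.3, 4.6, 15.8, 2.4, 2.217),  # onset variability
            (256.0, 30.4, 420.1, 32.2, -3.705),  # rotarod latency
        ],
    )
    def test_group_summary_statistics_reproduce(self, m1, s1, m2, s2, expected_t):
        res = t_from_summary(
            GroupSummary("ctl", m1, s1, 8), GroupSummary("trt", m2, s2, 8)
        )
        assert res.statistic == pytest.approx(expected_t, abs=0.005)
        assert res.df == (14.0,)

    def test_identical_summaries_give_t0_p1(self):
        g = GroupSummary("g", 5.0, 1.0, 8)
        res = t_from_summary(g, g)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_sems_with_unequal_means_undefined(self):
        with pytest.raises(ZeroDivisionError):
            t_from_summary(GroupSummary("a", 1, 0, 8), GroupSummary("b", 2, 0, 8))
        res = t_from_summary(GroupSummary("a", 1, 0, 8), GroupSummary("b", 1, 0, 8))
        assert res.statistic == 0.0


class TestRawT:
    def test_identical_groups_give_zero(self):
        res = t_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_agrees_with_summary_t_at_equal_n(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1.3, 8)
            raw = t_two_sample(x, y, mode="pooled")
            summ = t_from_summary(
                GroupSummary.from_values("x", x), GroupSummary.from_values("y", y)
            )
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
            assert raw.df == summ.df

    def test_welch_and_ranksum_modes(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 3, 12)
        assert t_two_sample(x, y, mode="welch").test_name == "t (Welch)"
        u = t_two_sample(x, y, mode="ranksum")
        assert u.test_name == "Mann-Whitney U"
        assert 0 <= u.statistic <= 8 * 12

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            t_two_sample([1.0, 1.0], [2.0, 2.0])


class TestRmAnova:
    @staticmethod
    def long_table(rng, n_per_group=8, n_time=6, treat_effect=0.0, time_effect=0.0):
        rows = []
        for g, grp in enumerate(["a", "b"]):
            for s in range(n_per_group):
                subj_offset = rng.normal(0, 1)
                for t in range(n_time):
                    rows.append(
                        {
                            "animal": f"{grp}{s}",
                            "treatment": grp,
                            "time": t,
                            "value": rng.normal(0, 1)
                            + subj_offset
                            + treat_effect * g
                            + time_effect * np.sin(t),
                        }
                    )
        return pd.DataFrame(rows)

    def test_constant_response_gives_zero_f(self):
        df = self.long_table(np.random.default_rng(0))
        df["value"] = 3.0
        res = two_way_rm_anova(df)
        assert all(r.statistic == 0.0 for r in res.values())

    def test_agrees_with_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = self.long_table(rng, treat_effect=0.8, time_effect=0.5)
        mine = two_way_rm_anova(df)
        ref = pg.mixed_anova(
            data=df, dv="value", within="time", subject="animal", between="treatment"
        ).set_index("Source")
        assert mine["treatment"].statistic == pytest.approx(ref.loc["treatment", "F"], rel=1e-9)
        assert mine["time"].statistic == pytest.approx(ref.loc["time", "F"], rel=1e-9)
        assert mine["interaction"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert mine["treatment"].df == (ref.loc["treatment", "DF1"], ref.loc["treatment", "DF2"])
        assert mine["time"].p_value == pytest.approx(ref.loc["time", "p_unc"], rel=1e-9)

    def test_treatment_f_is_squared_t_on_time_averages(self):
        rng = np.random.default_rng(4)
        df = self.long_table(rng, treat_effect=0.5)
        res = two_way_rm_anova(df)
        means = df.groupby(["animal", "treatment"], observed=True)["value"].mean().reset_index()
        t = t_two_sample(
            means.loc[means["treatment"] == "a", "value"],
            means.loc[means["treatment"] == "b", "value"],
        )
        assert res["treatment"].statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            df = self.long_table(rng, n_per_group=8, n_time=6)
            if two_way_rm_anova(df)["treatment"].p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_large_treatment_offset_always_detected(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            df = self.long_table(rng, treat_effect=5.0)
            assert two_way_rm_anova(df)["treatment"].p_value < 0.001

    def test_missing_cells_rejected(self):
        df = self.long_table(np.random.default_rng(7))
        with pytest.raises(ValueError):
            two_way_rm_anova(df.iloc[:-1])


class TestHolmSidak:
    def test_single_p_is_identity(self):
        reject, adj = holm_sidak([0.04])
        assert adj[0] == pytest.approx(0.04)
        assert reject[0]

    def test_small_case_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        p = [0.01, 0.04, 0.03]
        reject, adj = holm_sidak(p)
        ref_reject, ref_adj, _, _ = mt.multipletests(p, method="holm-sidak")
        np.testing.assert_allclose(adj, ref_adj, rtol=1e-12)
        np.testing.assert_array_equal(reject, ref_reject)
        # smallest p tested at exponent m
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 3)

    def test_all_ones_reject_nothing(self):
        reject, adj = holm_sidak([1.0, 1.0, 1.0])
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_never_more_rejections_than_unadjusted_and_monotone(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(0, 0.2, size=10)
            reject, adj = holm_sidak(p)
            assert reject.sum() <= (p < 0.05).sum()
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)
            assert np.all(adj >= p - 1e-15)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestScreens:
    def test_identical_groups_have_equal_variance(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = distribution_screens({"a": g, "b": g.copy()})
        assert res["brown_forsythe_p"] == pytest.approx(1.0)
        assert not res["unequal_variance"]

    def test_heavy_tails_rejected_more_often_than_normal(self):
        rng = np.random.default_rng(9)
        normal_rej = heavy_rej = 0
        for _ in range(200):
            res_n = distribution_screens({"g": rng.normal(0, 1, 50)})
            res_h = distribution_screens({"g": rng.standard_cauchy(50)})
            normal_rej += res_n["non_normal"]["g"]
            heavy_rej += res_h["non_normal"]["g"]
        assert heavy_rej > 5 * max(normal_rej, 1)
        assert normal_rej / 200 < 0.12


class TestObservedPower:
    def test_bounded_and_monotone_in_effect(self):
        p1 = observed_power_t(1.0, 8, 8)
        p2 = observed_power_t(3.0, 8, 8)
        assert 0 < p1 < p2 < 1
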