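"""Group-comparison battery and split-plot ANOVA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from irapfast import stats


class TestRankSum:
    def test_worked_tiny_example_with_tie(self):
        """x={0.1,0.2}, y={0.1,0.0}: 3 wins + half a tie -> W=3.5, r=0.875."""
        rep = stats.rank_sum_test([0.1, 0.2], [0.1, 0.0])
        assert rep.w_statistic == 3.5
        assert rep.r_estimator == pytest.approx(0.875)

    def test_published_w_to_r_conversion(self):
        """W = 682 at group sizes 33/25 gives r = 682/825 = 0.826."""
        r = 682 / (33 * 25)
        assert r == pytest.approx(0.826, abs=2e-3)
        # complete separation at those sizes saturates both W and r
        x = np.arange(33) + 100.0
        y = np.arange(25)
        rep = stats.rank_sum_test(x, y)
        assert rep.w_statistic == 33 * 25
        assert rep.r_estimator == 1.0

    def test_w_matches_scipy_u_statistic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=18), rng.normal(0.4, 1.0, size=14)
        rep = stats.rank_sum_test(x, y)
        u1 = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert rep.w_statistic == pytest.approx(u1)

    def test_exact_p_matches_brute_force_enumeration(self):
        """Exact two-sided p at tiny n equals full permutation enumeration."""
        x = [1.0, 3.0, 5.0]
        y = [2.0, 4.0]
        rep = stats.rank_sum_test(x, y)
        pooled = np.array(x + y)
        observed = abs(stats.mann_whitney_w(x, y) - len(x) * len(y) / 2)
        count = total = 0
        for idx in itertools.combinations(range(5), 3):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(5) if i not in idx]]
            dev = abs(stats.mann_whitney_w(xs, ys) - len(x) * len(y) / 2)
            count += dev >= observed - 1e-12
            total += 1
        assert rep.w_p_value == pytest.approx(count / total)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            stats.rank_sum_test([], [1.0])


class TestCliffsDelta:
    def test_complete_separation_reaches_minus_one(self):
        assert stats.cliffs_delta([1, 2, 3], [10, 11]) == -1.0

    @pytest.mark.parametrize(
        "delta,expected_a", [(0.754, 0.877), (0.493, 0.7465), (0.0, 0.5)]
    )
    def test_a_from_delta(self, delta, expected_a):
        assert stats.vd_a(delta) == pytest.approx(expected_a, abs=1e-4)

    def test_singleton_tie_gives_zero_delta_half_a(self):
        d = stats.cliffs_delta([1.0], [1.0])
        assert d == 0.0 and stats.vd_a(d) == 0.5

    def test_r_equals_a_on_shared_inputs(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0.5, 1, 20), rng.normal(size=15)
        rep = stats.rank_sum_test(x, y)
        assert rep.r_estimator == pytest.approx(
            stats.vd_a(stats.cliffs_delta(x, y))
        )


class TestWelch:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = stats.welch_t(x, x)
        assert rep.t_statistic == 0.0 and rep.cohens_d == 0.0

    def test_published_summary_moments(self):
        """(0.10, 0.29, 28) vs (-0.43, 0.35, 20): t ~ 5.53, d ~ 1.66."""
        rep = stats.welch_t_from_stats(0.10, 0.29, 28, -0.43, 0.35, 20)
        assert rep.t_statistic == pytest.approx(5.53, abs=0.05)
        assert rep.cohens_d == pytest.approx(1.66, abs=0.05)
        assert 30 < rep.t_df < 46  # fractional, unequal-variance form

    def test_unit_shift_of_common_sd_gives_d_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sd = x.std(ddof=1)
        rep = stats.welch_t(x + sd, x)
        assert rep.cohens_d == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=12), rng.normal(1.0, 2.0, size=17)
        rep = stats.welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert rep.t_statistic == pytest.approx(ref.statistic)
        assert rep.t_p_value == pytest.approx(ref.pvalue)

    def test_zero_variance_everywhere_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            stats.welch_t([1.0, 1.0], [2.0, 2.0])


class TestOneSampleT:
    def test_all_zero_scores(self):
        t, df, p = stats.one_sample_t([0.0, 0.0, 0.0])
        assert t == 0.0 and df == 2 and p == 1.0

    def test_constant_nonzero_scores_error(self):
        with pytest.raises(ValueError):
            stats.one_sample_t([1.0, 1.0, 1.0, 1.0])

    def test_matches_direct_formula(self):
        x = np.array([0.3, -0.1, 0.4, 0.2, 0.6])
        t, df, _ = stats.one_sample_t(x)
        assert t == pytest.approx(
            x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        )
        assert df == 4


class TestSpearman:
    def test_monotone_pairs(self):
        a = np.arange(10.0)
        rho, _ = stats.spearman_rho(a, np.exp(a))
        assert rho == pytest.approx(1.0)
        rho, _ = stats.spearman_rho(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0])
        b = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        ra = sps.rankdata(a)  # midranks
        rb = sps.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        rho, _ = stats.spearman_rho(a, b)
        assert rho == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _toy_scores(n1=3, n2=3, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=(n1 + n2, 4))
    y[n1:] -= 0.8  # group shift
    y[:, 0] += 0.5  # measure structure
    scores = pd.DataFrame(y, columns=["m1", "m2", "m3", "m4"])
    groups = pd.Series(["a"] * n1 + ["b"] * n2)
    return scores, groups


def _cellmeans_oracle(scores, groups):
    """Brute-force balanced split-plot SS from explicit marginal means."""
    y = scores.to_numpy()
    g = np.asarray(groups)
    levels = sorted(set(g))
    n = (g == levels[0]).sum()
    assert all((g == gl).sum() == n for gl in levels)  # balanced only
    a, b = len(levels), y.shape[1]
    grand = y.mean()
    subj = y.mean(axis=1)
    gm = np.array([y[g == gl].mean() for gl in levels])
    mm = y.mean(axis=0)
    cm = np.array([y[g == gl].mean(axis=0) for gl in levels])
    ss_group = n * b * ((gm - grand) ** 2).sum()
    ss_subj = b * sum(
        ((subj[g == gl] - gm[i]) ** 2).sum() for i, gl in enumerate(levels)
    )
    ss_meas = n * a * ((mm - grand) ** 2).sum()
    ss_inter = n * ((cm - gm[:, None] - mm[None, :] + grand) ** 2).sum()
    ss_resid = ((y - subj[:, None] - np.repeat(cm, n, axis=0)
                 + np.repeat(gm, n)[:, None]) ** 2).sum()
    return ss_group, ss_subj, ss_meas, ss_inter, ss_resid


class TestSplitPlotAnova:
    def test_toy_matches_cell_means_oracle(self):
        scores, groups = _toy_scores()
        fit = stats.split_plot_anova(scores, groups)
        ss_group, ss_subj, ss_meas, ss_inter, ss_resid = _cellmeans_oracle(
            scores, groups
        )
        assert fit.table.loc["group", "sum_sq"] == pytest.approx(ss_group)
        assert fit.table.loc["measure", "sum_sq"] == pytest.approx(ss_meas)
        assert fit.table.loc["interaction", "sum_sq"] == pytest.approx(ss_inter)
        assert fit.ms_resid * fit.df_resid == pytest.approx(ss_resid)
        assert fit.ms_subject * fit.df_subject == pytest.approx(ss_subj)

    def test_matches_pingouin_mixed_anova_balanced(self):
        pingouin = pytest.importorskip("pingouin")
        scores, groups = _toy_scores(n1=6, n2=6, seed=4)
        fit = stats.split_plot_anova(scores, groups)
        long = scores.assign(subject=range(12), group=groups).melt(
            id_vars=["subject", "group"], var_name="measure", value_name="y"
        )
        aov = pingouin.mixed_anova(
            data=long, dv="y", within="measure", subject="subject", between="group"
        ).set_index("Source")
        assert fit.table.loc["group", "F"] == pytest.approx(
            float(aov.loc["group", "F"])
        )
        assert fit.table.loc["measure", "F"] == pytest.approx(
            float(aov.loc["measure", "F"])
        )
        assert fit.table.loc["interaction", "F"] == pytest.approx(
            float(aov.loc["Interaction", "F"])
        )

    def test_unbalanced_groups_match_type3_ols_oracle(self):
        """Within-stratum SS equal OLS Type III (sum-to-zero) sums of squares,
        the convention the usual mixed-model ANOVA table reports."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        scores, groups = _toy_scores(n1=7, n2=5, seed=4)
        fit = stats.split_plot_anova(scores, groups)
        long = scores.assign(subject=range(12), group=groups).melt(
            id_vars=["subject", "group"], var_name="measure", value_name="y"
        )
        ols = smf.ols("y ~ C(group, Sum)*C(measure, Sum)", data=long).fit()
        tab = anova_lm(ols, typ=3)
        assert fit.table.loc["group", "sum_sq"] == pytest.approx(
            tab.loc["C(group, Sum)", "sum_sq"]
        )
        assert fit.table.loc["measure", "sum_sq"] == pytest.approx(
            tab.loc["C(measure, Sum)", "sum_sq"]
        )
        assert fit.table.loc["interaction", "sum_sq"] == pytest.approx(
            tab.loc["C(group, Sum):C(measure, Sum)", "sum_sq"]
        )

    def test_df_pattern_for_balanced_design(self):
        scores, groups = _toy_scores(n1=24, n2=24, seed=1)
        fit = stats.split_plot_anova(scores, groups)
        n = 48
        assert fit.table.loc["group", ["df_num", "df_den"]].tolist() == [1, n - 2]
        assert fit.table.loc["measure", ["df_num", "df_den"]].tolist() == [
            3, 3 * (n - 2)
        ]
        assert fit.table.loc["interaction", "df_den"] == 3 * (n - 2)

    def test_all_equal_observations_reported_undefined(self):
        scores = pd.DataFrame(np.ones((6, 4)), columns=list("wxyz"))
        fit = stats.split_plot_anova(scores, pd.Series(list("aaabbb")))
        assert (fit.table["sum_sq"] == 0).all()
        assert fit.table["F"].isna().all()

    def test_pure_group_shift_large_group_f_null_interaction(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(40, 4))
        y[20:] += 2.0
        fit = stats.split_plot_anova(
            pd.DataFrame(y, columns=list("wxyz")),
            pd.Series(["a"] * 20 + ["b"] * 20),
        )
        assert fit.table.loc["group", "F"] > 30
        assert fit.table.loc["interaction", "F"] < 5

    def test_participant_order_permutation_changes_nothing(self):
        scores, groups = _toy_scores(n1=6, n2=4, seed=2)
        fit1 = stats.split_plot_anova(scores, groups)
        perm = np.random.default_rng(0).permutation(len(scores))
        fit2 = stats.split_plot_anova(
            scores.iloc[perm].reset_index(drop=True),
            groups.iloc[perm].reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(fit1.table, fit2.table)

    def test_ss_additivity_in_within_stratum_when_balanced(self):
        scores, groups = _toy_scores(n1=5, n2=5, seed=3)
        fit = stats.split_plot_anova(scores, groups)
        y = scores.to_numpy()
        within_total = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum()
        parts = (
            fit.table.loc["measure", "sum_sq"]
            + fit.table.loc["interaction", "sum_sq"]
            + fit.ms_resid * fit.df_resid
        )
        assert parts == pytest.approx(within_total)

    def test_incomplete_data_rejected(self):
        scores, groups = _toy_scores()
        scores.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="mixed-model"):
            stats.split_plot_anova(scores, groups)


class TestPairwiseContrasts:
    def test_identical_measure_columns_give_zero_t_unit_p(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=8)
        scores = pd.DataFrame(
            {"m1": base, "m2": base, "m3": base + rng.normal(0, 1, 8),
             "m4": base - 1.0}
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        fit = stats.split_plot_anova(scores, groups)
        out = stats.pairwise_contrasts(fit)
        row = out["within"].query("group == 'a' and contrast == 'm1 - m2'").iloc[0]
        assert row.t == pytest.approx(0.0)
        assert row.p_tukey == pytest.approx(1.0)

    def test_within_estimates_match_cell_mean_differences(self):
        scores, groups = _toy_scores(n1=4, n2=4, seed=6)
        fit = stats.split_plot_anova(scores, groups)
        out = stats.pairwise_contrasts(fit)
        for _, row in out["within"].iterrows():
            m_i, m_j = row.contrast.split(" - ")
            expected = (
                fit.cell_means.loc[row.group, m_i]
                - fit.cell_means.loc[row.group, m_j]
            )
            assert row.estimate == pytest.approx(expected)
            assert row.t == pytest.approx(expected / row.se)

    def test_tukey_adjustment_never_below_unadjusted(self):
        scores, groups = _toy_scores(n1=5, n2=5, seed=7)
        fit = stats.split_plot_anova(scores, groups)
        out = stats.pairwise_contrasts(fit)
        for _, row in out["within"].iterrows():
            raw = 2 * sps.t.sf(abs(row.t), row.df)
            assert row.p_tukey >= raw - 1e-12

    def test_bonferroni_cells_cover_means(self):
        scores, groups = _toy_scores(n1=6, n2=6, seed=9)
        fit = stats.split_plot_anova(scores, groups)
        out = stats.pairwise_contrasts(fit)
        for _, row in out["cell_means"].iterrows():
            assert row.ci_low <= row["mean"] <= row.ci_high
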