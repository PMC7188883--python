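import numpy as np
import pytest

from tiltadapt.stats import (
    anova_tukey,
    correlations,
    significant_window,
    two_sample_t,
    two_sample_t_from_stats,
    window_mean,
    zscore_within_group,
)


def anova_f_textbook(groups):
    """Sums-of-squares one-way ANOVA F, written independently."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestSignificantWindow:
    def test_null_data_gives_no_window(self):
        rng = np.random.default_rng(0)
        curves = rng.normal(0, 1, (18, 40))
        res = significant_window(curves, alpha=0.01)
        assert res.window is None

    def test_schedule_tracking_window_covers_large_rotations(self, schedule_cw):
        rng = np.random.default_rng(1)
        curves = schedule_cw + rng.normal(0, 1, (18, 40))
        res = significant_window(curves, alpha=0.01)
        assert res.window is not None
        covered = set(res.trials.tolist())
        big = {t + 1 for t in range(40) if schedule_cw[t] >= 5}
        assert big <= covered

    def test_vacuous_alpha_spans_all_trials(self):
        rng = np.random.default_rng(2)
        curves = rng.normal(0, 1, (5, 40))
        assert significant_window(curves, alpha=1.0).window == (1, 40)

    def test_bonferroni_never_longer_than_uncorrected(self, schedule_cw):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            curves = 0.3 * schedule_cw + rng.normal(0, 2, (10, 40))
            corrected = significant_window(curves, correction="bonferroni")
            raw = significant_window(curves, correction="none")
            assert len(corrected.significant_trials) <= len(raw.significant_trials)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            significant_window(np.zeros((1, 40)))


class TestWindowMean:
    def test_constant_curve(self):
        assert window_mean(np.full(40, 7.0), (3, 17)) == 7.0

    def test_schedule_over_mid_window(self, schedule_cw):
        # triangle arithmetic: sum(p_12..p_35) = 159 over 24 trials
        assert window_mean(schedule_cw, (12, 35)) == pytest.approx(159.0 / 24.0)

    def test_missing_entries_skipped(self):
        curve = np.full(40, 4.0)
        curve[12] = np.nan
        assert window_mean(curve, (12, 15)) == pytest.approx(4.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_mean(np.zeros(40), None)


class TestAnovaTukey:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = anova_tukey({"a": g, "b": g, "c": g})
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for p in res.tukey_p.values())

    def test_df_for_three_by_eighteen(self):
        rng = np.random.default_rng(3)
        res = anova_tukey({k: rng.normal(size=18) for k in "abc"})
        assert res.df == (2, 51)

    def test_matches_textbook_f_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            groups = {
                k: rng.normal(rng.uniform(-2, 2), 1.0, rng.integers(3, 12))
                for k in "abc"
            }
            res = anova_tukey(groups)
            expected = anova_f_textbook([np.asarray(v) for v in groups.values()])
            assert res.F == pytest.approx(expected, abs=1e-9 * max(1, expected))

    def test_tukey_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 18)
        res = anova_tukey({"a": base, "b": base + 0.5, "c": base + 2.0})
        assert res.tukey_p[("a", "c")] < res.tukey_p[("a", "b")]

    def test_all_constant_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 1], "b": [2, 2], "c": [3, 3]})


class TestTwoSampleT:
    def test_identical_summaries(self):
        t, df, p = two_sample_t_from_stats(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_age_comparison_from_published_summaries(self):
        _, df, p = two_sample_t_from_stats(70.06, 7.34, 18, 75.67, 12.70, 18)
        assert df == 34
        assert p == pytest.approx(0.1138, abs=0.005)

    def test_mmse_comparison_from_published_summaries(self):
        _, _, p = two_sample_t_from_stats(27.78, 2.07, 18, 27.72, 2.45, 18)
        assert p == pytest.approx(0.9418, abs=0.01)

    def test_raw_samples_equal_summary_path(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 15)
        t_raw, df_raw, p_raw = two_sample_t(x, y)
        t_s, df_s, p_s = two_sample_t_from_stats(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert (t_raw, df_raw, p_raw) == pytest.approx((t_s, df_s, p_s))

    def test_welch_differs_with_unequal_variances(self):
        _, df_p, p_pooled = two_sample_t_from_stats(0, 1.0, 10, 1, 5.0, 20)
        _, df_w, p_welch = two_sample_t_from_stats(0, 1.0, 10, 1, 5.0, 20, equal_var=False)
        assert df_w != df_p and p_welch != p_pooled

    def test_degenerate_conventions(self):
        assert two_sample_t_from_stats(3, 0, 5, 3, 0, 5)[2] == 1.0
        assert two_sample_t_from_stats(3, 0, 5, 4, 0, 5)[2] == 0.0


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlations(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.arange(1.0, 11.0)
        res = correlations(x, x**2)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.pearson_r < 1.0

    def test_hand_computed_five_points(self):
        # cov/sd arithmetic on {(1,2),(2,1),(3,4),(4,3),(5,5)} gives r = 0.8
        res = correlations([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.pearson_r == pytest.approx(0.8, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlations([1, 1, 1], [1, 2, 3])


class TestZScoreWithinGroup:
    def test_per_group_mean_zero_sd_one(self):
        rng = np.random.default_rng(7)
        values = rng.normal(50, 20, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        z = zscore_within_group(values, groups)
        for g in "abc":
            sub = z[groups == g]
            assert abs(sub.mean()) < 1e-12
            assert abs(sub.std(ddof=1) - 1) < 1e-12

    def test_group_offsets_invisible_after_normalization(self):
        rng = np.random.default_rng(8)
        values = rng.normal(100, 15, 24)
        groups = np.repeat(["a", "b"], 12)
        shifted = values.copy()
        shifted[groups == "a"] += 100.0
        np.testing.assert_allclose(
            zscore_within_group(values, groups), zscore_within_group(shifted, groups), atol=1e-12
        )

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            zscore_within_group([1, 1, 2, 3], ["a", "a", "b", "b"])

    def test_independent_metrics_stay_uncorrelated(self):
        # null check: movement time and amplitude generated independently
        # show no correlation after within-group normalization.  At
        # n = 54 the null r has SE 1/sqrt(51) ~ 0.14, so |r| < 0.2 holds
        # for ~85% of draws; require a clear majority plus a small mean.
        hits, rs = 0, []
        means = {"a": 109.0, "b": 96.0, "c": 51.0}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = np.repeat(list(means), 18)
            mt = np.concatenate([rng.normal(means[g], 20, 18) for g in means])
            amp = np.concatenate([rng.normal(0.8, 0.15, 18) for _ in means])
            z = zscore_within_group(mt, groups)
            r = correlations(z, amp).pearson_r
            rs.append(r)
            if abs(r) < 0.2:
                hits += 1
        assert hits >= 15
        assert abs(np.mean(rs)) < 0.1
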