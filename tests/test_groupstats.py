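"""Assumption checks, omnibus dispatch, and post-hoc procedures."""
import numpy as np
import pytest
from scipy import stats

from eyemorph import check_assumptions, compare_groups
from eyemorph.groupstats import dunn_test, variance_ratio_test
from eyemorph.types import DegenerateInputError


class TestAssumptions:
    def test_gaussian_samples_usually_pass(self):
        """Two nested normality tests at alpha=0.05 each pass jointly ~90% of draws."""
        rng = np.random.default_rng(1)
        passes = sum(
            all(check_assumptions({"g": rng.normal(0, 1, 60)})[0].values())
            for _ in range(300)
        )
        assert 0.84 < passes / 300 < 0.98

    def test_exponential_samples_usually_fail(self):
        rng = np.random.default_rng(2)
        passes = sum(
            all(check_assumptions({"g": rng.exponential(1.0, 50)})[0].values())
            for _ in range(200)
        )
        assert passes / 200 < 0.15

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(3)
        _, equal = check_assumptions(
            {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 4, 40)}
        )
        assert not equal
        _, equal2 = check_assumptions(
            {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40)}
        )
        assert equal2

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            check_assumptions({"a": [2.0, 2.0, 2.0, 2.0]})

    def test_variance_ratio_matches_f_distribution(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 21), rng.normal(0, 1, 16)
        F, p = variance_ratio_test(a, b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        assert F == pytest.approx(max(va, vb) / min(va, vb))
        assert 0 <= p <= 1


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        comp = compare_groups({"a": vals, "b": vals})
        assert comp.statistic == pytest.approx(0.0)
        assert comp.p == pytest.approx(1.0)
        assert comp.omnibus in ("t_test", "welch_t_test")

    def test_two_gaussian_groups_use_pooled_t(self):
        rng = np.random.default_rng(6)
        comp = compare_groups(
            {"a": rng.normal(0, 1, 30), "b": rng.normal(1, 1, 30)}
        )
        assert comp.omnibus == "t_test"
        assert comp.df == 58
        assert comp.p < 0.01

    def test_unequal_variance_dispatches_welch(self):
        rng = np.random.default_rng(7)
        comp = compare_groups(
            {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 5, 40)}
        )
        assert comp.omnibus == "welch_t_test"

    def test_three_gaussian_groups_use_anova_with_bonferroni(self):
        rng = np.random.default_rng(8)
        comp = compare_groups(
            {g: rng.normal(m, 1, 20) for g, m in [("a", 0), ("b", 0.2), ("c", 3)]}
        )
        assert comp.omnibus == "anova"
        assert len(comp.posthoc) == 3
        assert all(p.method == "bonferroni" for p in comp.posthoc)
        by_pair = {p.pair: p.p_adjusted for p in comp.posthoc}
        assert by_pair[("a", "c")] < 0.001
        assert by_pair[("a", "b")] > 0.05

    def test_skewed_groups_dispatch_kruskal_with_dunn(self):
        rng = np.random.default_rng(9)
        comp = compare_groups(
            {g: rng.exponential(s, 40) for g, s in [("a", 1), ("b", 1), ("c", 4)]}
        )
        assert comp.omnibus == "kruskal_wallis"
        assert all(p.method == "dunn" for p in comp.posthoc)

    def test_anova_F_equals_t_squared_on_two_groups(self):
        rng = np.random.default_rng(10)
        samples = {"a": rng.normal(0, 1, 15), "b": rng.normal(0.8, 1, 12)}
        t_comp = compare_groups(samples, force_method="t_test")
        f_comp = compare_groups(samples, force_method="anova")
        assert f_comp.statistic == pytest.approx(t_comp.statistic**2, rel=1e-10)
        assert f_comp.p == pytest.approx(t_comp.p, rel=1e-10)

    def test_kruskal_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        samples = {g: rng.uniform(0, 10, 25) for g in "abc"}
        k1 = compare_groups(samples, force_method="kruskal_wallis").statistic
        k2 = compare_groups(
            {g: np.exp(v) for g, v in samples.items()}, force_method="kruskal_wallis"
        ).statistic
        assert k1 == pytest.approx(k2, rel=1e-12)

    def test_anova_type_I_error_near_alpha(self):
        rng = np.random.default_rng(12)
        reps, rejections = 500, 0
        for _ in range(reps):
            samples = {g: rng.normal(0, 1, 12) for g in "abc"}
            comp = compare_groups(samples, force_method="anova")
            rejections += comp.p < 0.05
        assert abs(rejections / reps - 0.05) < 0.03

    def test_insufficient_group_size_errors(self):
        with pytest.raises(DegenerateInputError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    def test_tukey_on_request_matches_scipy(self):
        rng = np.random.default_rng(13)
        samples = {g: rng.normal(m, 1, 15) for g, m in [("a", 0), ("b", 1), ("c", 2)]}
        comp = compare_groups(samples, posthoc="tukey")
        ref = stats.tukey_hsd(*samples.values())
        got = {p.pair: p.p_adjusted for p in comp.posthoc}
        assert got[("a", "b")] == pytest.approx(ref.pvalue[0, 1])
        assert got[("b", "c")] == pytest.approx(ref.pvalue[1, 2])


class TestPosthocAdjustment:
    def test_bonferroni_definition_and_cap(self):
        rng = np.random.default_rng(14)
        samples = {g: rng.normal(0, 1, 10) for g in "abc"}
        comp = compare_groups(samples, posthoc="bonferroni")
        # recompute raw pairwise t with the pooled MSE and check x3 capping
        names = list(samples)
        N = 30
        sse = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
        mse = sse / (N - 3)
        for res in comp.posthoc:
            a, b = res.pair
            xa, xb = samples[a], samples[b]
            t = (xa.mean() - xb.mean()) / np.sqrt(mse * (1 / 10 + 1 / 10))
            raw = 2 * stats.t.sf(abs(t), N - 3)
            assert res.p_adjusted == pytest.approx(min(1.0, raw * 3))
            assert res.p_adjusted >= raw

    def test_dunn_two_groups_matches_rank_sum_normal_approximation(self):
        """For k=2 Dunn's z equals the asymptotic Mann-Whitney z (no continuity)."""
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 18), rng.normal(0.9, 1, 14)
        res = dunn_test({"a": a, "b": b})[0]
        mw = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        n1, n2 = len(a), len(b)
        z_mw = (mw.statistic - n1 * n2 / 2) / np.sqrt(
            n1 * n2 * (n1 + n2 + 1) / 12.0
        )
        assert abs(res.statistic) == pytest.approx(abs(z_mw), rel=1e-10)

    def test_dunn_tie_correction_with_heavily_tied_data(self):
        a = [1, 1, 2, 2, 3, 3, 3]
        b = [2, 3, 3, 4, 4, 5, 5]
        c = [4, 5, 5, 6, 6, 6, 7]
        out = dunn_test({"a": a, "b": b, "c": c})
        assert len(out) == 3
        assert all(0 <= r.p_adjusted <= 1 for r in out)
        far = {r.pair: abs(r.statistic) for r in out}
        assert far[("a", "c")] > far[("a", "b")]
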