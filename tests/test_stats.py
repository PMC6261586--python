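"""Summaries, t-tests, effect sizes, percent conventions, responder counts.

t-test p-values are cross-checked against independent routes: the direct
t = mean/(s/sqrt(n)) formula with the regularized-incomplete-beta tail for
paired data, and scipy's two-sample machinery for the unpaired case.
"""

import math

import numpy as np
import pytest
from scipy import special
from scipy import stats as sps

from tgskit.errors import UndefinedStatisticError, ValidationError
from tgskit.io import Subject
from tgskit.stats import (
    bonferroni_alpha,
    ci_mean_t,
    classify_effect,
    cohen_d_independent,
    cohen_d_prepost,
    group_summary,
    independent_t,
    mean_individual_percent_improvement,
    paired_t,
    percent_improvement_of_means,
    responder_counts,
)


class TestCiMeanT:
    @pytest.mark.parametrize(
        "mean,sd,n,expected",
        [
            (67, 33, 6, (40, 94)),
            (382, 270, 42, (312, 452)),
            (560, 225, 13, (449, 671)),
        ],
    )
    def test_reproduces_whole_metre_intervals(self, mean, sd, n, expected):
        lo, hi = ci_mean_t(mean, sd, n, 0.90)
        assert (round(lo), round(hi)) == expected

    def test_symmetric_about_mean(self):
        lo, hi = ci_mean_t(0, 1, 4, 0.90)
        assert lo == pytest.approx(-hi)

    def test_zero_sd_gives_zero_width(self):
        assert ci_mean_t(5.0, 0.0, 10, 0.90) == (5.0, 5.0)

    def test_n_below_two_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ci_mean_t(0, 1, 1, 0.90)


class TestGroupSummary:
    def test_matches_summary_statistic_route(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1000, 300, size=17)
        s = group_summary(x, 0.90)
        assert s.mean == pytest.approx(x.mean())
        assert s.sd == pytest.approx(x.std(ddof=1))
        assert (s.ci_low, s.ci_high) == pytest.approx(ci_mean_t(s.mean, s.sd, s.n, 0.90))
        assert s.ci_low <= s.mean <= s.ci_high

    def test_coverage_of_90_percent_interval(self):
        """Empirical coverage of the t interval is 0.90 +/- 0.02 over 2000 draws."""
        rng = np.random.default_rng(42)
        n, mu = 12, 50.0
        samples = rng.normal(mu, 7.0, size=(2000, n))
        means = samples.mean(axis=1)
        sds = samples.std(axis=1, ddof=1)
        half = sps.t.ppf(0.95, n - 1) * sds / math.sqrt(n)
        coverage = ((means - half <= mu) & (mu <= means + half)).mean()
        assert abs(coverage - 0.90) <= 0.02


class TestPairedT:
    def test_no_change_gives_statistic_zero_p_one(self):
        r = paired_t([100, 200, 300], [100, 200, 300])
        assert (r.statistic, r.p) == (0.0, 1.0)
        assert r.degenerate_variance

    def test_constant_shift_is_degenerate_with_p_zero(self):
        r = paired_t([100, 200, 300], [110, 210, 310])
        assert math.isinf(r.statistic)
        assert r.p == 0.0
        assert r.degenerate_variance

    def test_p_matches_incomplete_beta_oracle(self):
        rng = np.random.default_rng(7)
        pre = rng.normal(1000, 300, 10)
        post = pre + rng.normal(50, 120, 10)
        r = paired_t(pre, post)
        d = post - pre
        t = d.mean() / (d.std(ddof=1) / math.sqrt(10))
        df = 9
        p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
        assert r.statistic == pytest.approx(t, abs=1e-12)
        assert r.p == pytest.approx(p, abs=1e-10)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        pre = rng.normal(0, 1, 15)
        post = rng.normal(0.4, 1, 15)
        ours = paired_t(pre, post)
        ref = sps.ttest_rel(post, pre)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValidationError):
            paired_t([1, 2], [1, 2, 3])
        with pytest.raises(UndefinedStatisticError):
            paired_t([1], [2])


class TestIndependentT:
    def test_identical_samples_give_zero_statistic(self):
        r = independent_t([1, 2, 3], [1, 2, 3])
        assert (r.statistic, r.p) == (0.0, 1.0)

    def test_pooled_statistic_matches_hand_formula(self):
        a, b = [0, 0, 1, 1], [10, 10, 11, 11]
        # means 0.5 and 10.5; pooled variance = (3*1/3 + 3*1/3)/6 = 1/3
        expected = 10.0 / math.sqrt((1 / 3) * 0.5)
        r = independent_t(a, b)
        assert r.statistic == pytest.approx(expected, abs=1e-10)
        assert r.df == 6

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 2, 11)
        assert independent_t(a, b).statistic == pytest.approx(
            independent_t(a + 100, b + 100).statistic, abs=1e-10
        )

    @pytest.mark.parametrize("welch", [False, True])
    def test_agrees_with_scipy(self, welch):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 9)
        b = rng.normal(0.8, 2.5, 14)
        ours = independent_t(a, b, welch=welch)
        ref = sps.ttest_ind(b, a, equal_var=not welch)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_single_observation_group_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            independent_t([1.0], [1, 2, 3])


class TestBonferroni:
    def test_six_tests_print_as_0_008(self):
        assert round(bonferroni_alpha(0.05, 6), 3) == 0.008

    @pytest.mark.parametrize("alpha,k,expected", [(0.05, 1, 0.05), (0.05, 10, 0.005)])
    def test_simple_divisions(self, alpha, k, expected):
        assert bonferroni_alpha(alpha, k) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_alpha(0.05, 0)


class TestCohenD:
    def test_prepost_equal_sds_reduces_to_change_over_sd(self):
        e = cohen_d_prepost(100.0, 50.0, 130.0, 50.0)
        assert e.d == pytest.approx(30.0 / 50.0, abs=1e-15)

    def test_prepost_equal_means_is_trivial(self):
        e = cohen_d_prepost(100, 20, 100, 30)
        assert (e.d, e.band) == (0.0, "trivial")

    def test_prepost_both_sds_zero_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_d_prepost(100, 0, 120, 0)

    def test_independent_symmetric_and_shift_invariant(self):
        a = cohen_d_independent(67, 33, 6, 364, 248, 23)
        b = cohen_d_independent(364, 248, 23, 67, 33, 6)
        c = cohen_d_independent(67 + 500, 33, 6, 364 + 500, 248, 23)
        assert a.d == pytest.approx(b.d) == pytest.approx(c.d)

    def test_independent_equal_means_is_zero(self):
        assert cohen_d_independent(50, 10, 5, 50, 20, 8).d == 0.0

    def test_independent_zero_pooled_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_d_independent(1, 0, 5, 2, 0, 5)


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "d,band",
        [
            (0.0, "trivial"), (0.19, "trivial"), (0.2, "small"), (0.23, "small"),
            (0.5, "moderate"), (0.79, "moderate"), (0.8, "large"), (1.12, "large"),
            (1.2, "very large"), (2.0, "very large"), (2.01, "huge"), (2.59, "huge"),
            (-1.12, "large"),  # bands act on |d|
        ],
    )
    def test_bands_are_contiguous_half_open(self, d, band):
        assert classify_effect(d) == band

    def test_every_finite_d_gets_exactly_one_band(self):
        labels = {"trivial", "small", "moderate", "large", "very large", "huge"}
        for d in np.linspace(-5, 5, 2001):
            assert classify_effect(float(d)) in labels


class TestPercentConventions:
    @pytest.mark.parametrize(
        "improvement,pre,whole_pct",
        [(560, 969, 58), (364, 1045, 35), (67, 1006, 7), (0, 1000, 0)],
    )
    def test_ratio_of_means(self, improvement, pre, whole_pct):
        assert round(percent_improvement_of_means(improvement, pre)) == whole_pct

    def test_ratio_of_means_requires_positive_baseline(self):
        with pytest.raises(ValidationError):
            percent_improvement_of_means(100, 0)

    def subjects(self, pairs):
        return [
            Subject(id=f"S{i}", genotypes={}, pre_yoyo=a, post_yoyo=b)
            for i, (a, b) in enumerate(pairs)
        ]

    def test_mean_individual_is_average_of_per_subject_ratios(self):
        assert mean_individual_percent_improvement(
            self.subjects([(100, 150), (200, 200)])
        ) == pytest.approx(25.0)

    def test_mean_individual_differs_from_ratio_of_means(self):
        """Low-baseline improvers pull the individual-mean convention above the
        ratio-of-means one; a cohort with known per-subject ratios shows both."""
        pairs = [(100, 200), (1000, 1100), (500, 600)]
        subs = self.subjects(pairs)
        individual = mean_individual_percent_improvement(subs)
        assert individual == pytest.approx((100.0 + 10.0 + 20.0) / 3)
        mean_pre = sum(p for p, _ in pairs) / 3
        mean_impr = sum(q - p for p, q in pairs) / 3
        assert percent_improvement_of_means(mean_impr, mean_pre) < individual

    def test_zero_baseline_subject_rejected(self):
        with pytest.raises(ValidationError):
            mean_individual_percent_improvement(self.subjects([(0, 100)]))


class TestResponderCounts:
    def test_strictly_greater_counting(self):
        assert responder_counts([100, 130, 600], (120, 500)) == {120.0: 2, 500.0: 1}

    def test_empty_improvements_all_zero(self):
        assert responder_counts([], (120, 500)) == {120.0: 0, 500.0: 0}

    def test_boundary_value_not_counted(self):
        assert responder_counts([120.0], (120,)) == {120.0: 0}

    def test_thresholds_required(self):
        with pytest.raises(ValidationError):
            responder_counts([1.0], ())
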