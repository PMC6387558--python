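"""Diagnostic accuracy and comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dlbpet.diagstats import (Confusion2x2, agreement_and_gain,
                              clopper_pearson, counts_from_percent,
                              delong_paired, mcnemar, pairwise_confusion,
                              pearson_chi2, performance, welch_t)


class TestPairwiseConfusion:
    LABEL_MAP = {"DLB": "DLB_LIKE", "ADD": "AD_LIKE", "PD": "PD_LIKE"}

    def test_third_pattern_labels_excluded(self):
        labels = (["DLB_LIKE"] * 64 + ["AD_LIKE"] * 8
                  + ["DLB_LIKE"] * 5 + ["PD_LIKE"] * 31)
        truth = ["DLB"] * 72 + ["PD"] * 36
        conf = pairwise_confusion(labels, truth, "DLB", "PD",
                                  label_map=self.LABEL_MAP)
        assert (conf.tp, conf.fn, conf.tn, conf.fp) == (64, 0, 31, 5)

    def test_without_third_labels_equals_naive(self):
        labels = ["DLB_LIKE"] * 9 + ["AD_LIKE"] * 3 + ["AD_LIKE"] * 7
        truth = ["DLB"] * 12 + ["ADD"] * 7
        conf = pairwise_confusion(labels, truth, "DLB", "ADD",
                                  label_map=self.LABEL_MAP)
        assert (conf.tp, conf.fn, conf.tn, conf.fp) == (9, 3, 7, 0)

    def test_everyone_excluded_raises(self):
        with pytest.raises(ValueError):
            pairwise_confusion(["PD_LIKE", "PD_LIKE"], ["DLB", "ADD"],
                               "DLB", "ADD", label_map=self.LABEL_MAP)


class TestPerformance:
    def test_published_dlb_vs_add_row(self):
        perf = performance(Confusion2x2(tp=64, fn=8, tn=57, fp=3))
        r = perf.rounded()
        assert r["sensitivity"] == 0.89
        assert r["specificity"] == 0.95
        assert r["accuracy"] == 0.92
        assert r["sensitivity_ci"] == (0.79, 0.95)

    def test_perfect_sensitivity_lower_bound_closed_form(self):
        n = 64
        perf = performance(Confusion2x2(tp=n, fn=0, tn=10, fp=2))
        assert perf.sensitivity == 1.0
        assert perf.sensitivity_ci[0] == pytest.approx(0.025 ** (1 / n),
                                                       rel=1e-9)
        assert perf.sensitivity_ci[1] == 1.0

    def test_clopper_pearson_matches_tail_search(self, rng):
        """Brute-force oracle: endpoints are where the binomial tail
        probability crosses alpha/2, searched on a 1e-5 grid."""
        for k, n in [(3, 17), (0, 9), (11, 11), (25, 40)]:
            lo, hi = clopper_pearson(k, n)
            grid = np.linspace(1e-6, 1 - 1e-6, 10 ** 5)
            upper_tail = stats.binom.sf(k - 1, n, grid)   # P(X >= k)
            lower_tail = stats.binom.cdf(k, n, grid)      # P(X <= k)
            lo_brute = 0.0 if k == 0 else grid[upper_tail >= 0.025].min()
            hi_brute = 1.0 if k == n else grid[lower_tail >= 0.025].max()
            assert lo == pytest.approx(lo_brute, abs=2e-5)
            assert hi == pytest.approx(hi_brute, abs=2e-5)

    def test_estimates_inside_intervals(self):
        perf = performance(Confusion2x2(tp=5, fn=2, tn=9, fp=1))
        for est, ci in [(perf.sensitivity, perf.sensitivity_ci),
                        (perf.specificity, perf.specificity_ci),
                        (perf.accuracy, perf.accuracy_ci)]:
            assert ci[0] <= est <= ci[1]
            assert 0.0 <= ci[0] <= ci[1] <= 1.0


class TestAgreement:
    def test_published_arithmetic(self):
        p_entry, p_test, gain = agreement_and_gain(44, 64, 72)
        assert round(100 * p_entry, 1) == 61.1
        assert round(100 * p_test, 2) == 88.89
        assert round(100 * gain, 1) == 45.5

    def test_equal_counts_zero_gain(self):
        assert agreement_and_gain(30, 30, 50)[2] == 0.0

    def test_doubling(self):
        assert agreement_and_gain(10, 20, 100)[2] == pytest.approx(1.0)

    def test_zero_entry_rejected(self):
        with pytest.raises(ValueError):
            agreement_and_gain(0, 10, 20)


class TestChi2:
    def test_published_values(self):
        assert pearson_chi2([[29, 2], [26, 15]])[0] == pytest.approx(
            8.887, abs=5e-4)
        assert pearson_chi2([[11, 2], [8, 15]])[0] == pytest.approx(
            8.276, abs=5e-4)

    def test_identical_proportions_zero(self):
        stat, p = pearson_chi2([[10, 30], [5, 15]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = [[7, 3], [2, 9]]
        base = pearson_chi2(t)[0]
        assert pearson_chi2([t[1], t[0]])[0] == pytest.approx(base)
        assert pearson_chi2(np.transpose(t))[0] == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [3, 4]])


class TestMcNemar:
    def test_corrected_arithmetic(self):
        assert mcnemar(10, 10)[0] == pytest.approx(0.05)

    def test_reconstructed_discordants_match_published(self):
        stat, p = mcnemar(5, 25)
        assert stat == pytest.approx(12.033, abs=5e-4)
        assert p < 0.001

    def test_symmetric_in_b_and_c(self):
        assert mcnemar(4, 19) == mcnemar(19, 4)

    def test_uncorrected(self):
        assert mcnemar(5, 25, continuity_corrected=False)[0] == \
            pytest.approx(400 / 30)

    def test_no_discordants_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(0, 0)


class TestDeLong:
    def test_identical_scores_degenerate(self):
        y = [True, True, False, False, True]
        s = [0.9, 0.8, 0.3, 0.2, 0.7]
        auc1, auc2, z, p = delong_paired(s, s, y)
        assert auc1 == auc2 == 1.0
        assert z == 0.0 and p == 1.0

    def test_auc_matches_pair_counting(self, rng):
        y = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        s1 = rng.normal(size=30) + y
        s2 = rng.normal(size=30) + 0.5 * y
        auc1, auc2, _, _ = delong_paired(s1, s2, y)
        for s, auc in [(s1, auc1), (s2, auc2)]:
            pos, neg = s[y], s[~y]
            brute = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            assert auc == pytest.approx(brute / (15 * 15), rel=1e-12)

    def test_variance_close_to_bootstrap(self, rng):
        """DeLong variance of the AUC difference vs 2000 bootstrap
        resamples on a fixed 30-subject instance."""
        y = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        s1 = rng.normal(size=30) + 1.2 * y
        s2 = 0.6 * s1 + rng.normal(size=30)

        auc1, auc2, z, _ = delong_paired(s1, s2, y)
        var_delong = ((auc1 - auc2) / z) ** 2

        def auc_of(s, yy):
            pos, neg = s[yy], s[~yy]
            return ((pos[:, None] > neg[None, :]).sum()
                    + 0.5 * (pos[:, None] == neg[None, :]).sum()) / (
                        len(pos) * len(neg))

        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, 30, 30)
            yy = y[idx]
            if yy.all() or not yy.any():
                continue
            diffs.append(auc_of(s1[idx], yy) - auc_of(s2[idx], yy))
        assert var_delong == pytest.approx(np.var(diffs), rel=0.2)

    def test_null_z_is_standard_normal(self, rng):
        """Kolmogorov-Smirnov check over 500 null simulations."""
        zs = []
        y = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        for _ in range(500):
            zs.append(delong_paired(rng.normal(size=40), rng.normal(size=40),
                                    y)[2])
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_paired([1, 2], [1, 2], [True, True])


class TestWelch:
    def test_identical_groups(self, rng):
        g = rng.normal(size=10)
        t, _, p = welch_t(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_summary_comparison(self):
        t, df, p = welch_t(summaries=((19.96, 4.39, 41), (16.24, 4.87, 31)))
        assert p <= 0.01
        assert t > 0

    def test_samples_and_summaries_agree(self, rng):
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        direct = welch_t(g1, g2)
        summary = welch_t(summaries=((g1.mean(), g1.std(ddof=1), 12),
                                     (g2.mean(), g2.std(ddof=1), 9)))
        assert direct == pytest.approx(summary, rel=1e-10)
        ref = stats.ttest_ind(g1, g2, equal_var=False)
        assert direct[0] == pytest.approx(ref.statistic, rel=1e-12)
        assert direct[2] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])


@settings(derandomize=True, max_examples=60)
@given(st.integers(1, 200), st.data())
def test_clopper_pearson_contains_point_estimate(n, data):
    """The exact interval always covers k/n and lies inside [0, 1]."""
    k = data.draw(st.integers(0, n))
    lo, hi = clopper_pearson(k, n)
    assert 0.0 <= lo <= k / n <= hi <= 1.0


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
def test_chi2_invariant_under_margin_permutations(cells):
    a, b, c, d = cells
    base = pearson_chi2([[a, b], [c, d]])[0]
    assert pearson_chi2([[c, d], [a, b]])[0] == pytest.approx(base)
    assert pearson_chi2([[a, c], [b, d]])[0] == pytest.approx(base)
    assert pearson_chi2([[b, a], [d, c]])[0] == pytest.approx(base)


def test_counts_from_percent_roundtrip():
    assert counts_from_percent(93.5, 31) == 29
    assert counts_from_percent(63.4, 41) == 26
    assert counts_from_percent(84.6, 13) == 11
    assert counts_from_percent(34.8, 23) == 8
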