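"""Exact binomial CIs, likelihood ratios, inclusive sensitivity, sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vcfval import (
    ComparisonRule,
    Table2x2,
    accuracy_summary,
    exact_binomial_ci,
    inclusive_sensitivity,
    likelihood_ratios,
    sample_size_for_lr,
)


def round_half_away(x: float, nd: int) -> float:
    q = 10**nd
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def cp_bisect(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Independent Clopper-Pearson oracle: bisection on the binomial tails."""
    alpha = 1.0 - level

    def bisect(f, lo, hi):
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # lower bound: largest p with P(X >= k | p) <= alpha/2
    low = 0.0 if k == 0 else bisect(lambda p: stats.binom.sf(k - 1, n, p) <= alpha / 2, 0.0, 1.0)
    # upper bound: smallest p with P(X <= k | p) <= alpha/2
    high = 1.0 if k == n else 1.0 - bisect(
        lambda q: stats.binom.cdf(k, n, 1.0 - q) <= alpha / 2, 0.0, 1.0
    )
    return low, high


class TestExactBinomialCI:
    def test_matches_tail_inversion_oracle_all_small_n(self):
        for n in range(1, 31):
            for k in range(n + 1):
                est = exact_binomial_ci(k, n)
                lo, hi = cp_bisect(k, n)
                assert est.ci_low == pytest.approx(lo, abs=1e-10)
                assert est.ci_high == pytest.approx(hi, abs=1e-10)

    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (149, 227, (0.59, 0.72)),  # any-VCF sensitivity
            (32, 50, (0.49, 0.77)),  # T8 per-level row
        ],
    )
    def test_printed_two_decimal_intervals(self, k, n, expected):
        est = exact_binomial_ci(k, n)
        assert (round_half_away(est.ci_low, 2), round_half_away(est.ci_high, 2)) == expected

    def test_degenerate_bounds(self):
        assert exact_binomial_ci(0, 10).ci_low == 0.0
        assert exact_binomial_ci(10, 10).ci_high == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(1, 0)
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 3)

    def test_coverage_is_conservative(self):
        # exact CIs cover at >= the nominal level
        rng = np.random.default_rng(424242)
        n = 100
        for p in (0.05, 0.5, 0.9):
            ks = rng.binomial(n, p, size=2000)
            lows = np.where(ks == 0, 0.0, stats.beta.ppf(0.025, ks, n - ks + 1))
            highs = np.where(ks == n, 1.0, stats.beta.ppf(0.975, ks + 1, n - ks))
            coverage = np.mean((lows <= p) & (p <= highs))
            assert coverage >= 0.95


class TestAccuracySummary:
    def test_any_vcf_printed_rounding(self, study_tables):
        summ = accuracy_summary(study_tables[ComparisonRule.ANY])
        assert round_half_away(summ["sensitivity"].point, 2) == 0.66
        assert round_half_away(summ["specificity"].point, 2) == 0.90

    def test_moderate_severe_printed_rounding(self, study_tables):
        summ = accuracy_summary(study_tables[ComparisonRule.MODERATE_OR_SEVERE])
        assert round_half_away(summ["sensitivity"].point, 2) == 0.78
        assert round_half_away(summ["specificity"].point, 2) == 0.87

    def test_perfect_test(self):
        summ = accuracy_summary(Table2x2(5, 0, 0, 5))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert summ[name].point == 1.0

    def test_zero_margin_flagged_or_strict_error(self):
        t = Table2x2(0, 0, 3, 7)  # no reference positives
        assert accuracy_summary(t)["sensitivity"] is None
        with pytest.raises(ValueError, match="sensitivity.*tp\\+fn"):
            accuracy_summary(t, strict=True)


class TestLikelihoodRatios:
    @pytest.mark.parametrize(
        "rule,expected",
        [(ComparisonRule.ANY, 6.88), (ComparisonRule.MODERATE_OR_SEVERE, 5.98)],
    )
    def test_printed_lr_pos(self, study_tables, rule, expected):
        lr = likelihood_ratios(study_tables[rule])["lr_pos"]
        assert round_half_away(lr.point, 2) == expected

    def test_uninformative_test(self):
        lrs = likelihood_ratios(Table2x2(5, 5, 5, 5))
        assert lrs["lr_pos"].point == pytest.approx(1.0)
        assert lrs["lr_neg"].point == pytest.approx(1.0)

    @given(
        tp=st.integers(1, 500), fn=st.integers(1, 500),
        fp=st.integers(1, 500), tn=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identities(self, tp, fn, fp, tn):
        t = Table2x2(tp, fn, fp, tn)
        lrs = likelihood_ratios(t)
        sens, spec = tp / (tp + fn), tn / (fp + tn)
        assert lrs["lr_pos"].point * (1 - spec) == pytest.approx(sens, abs=1e-12)
        assert lrs["lr_neg"].point * spec == pytest.approx(1 - sens, abs=1e-12)
        dor = lrs["lr_pos"].point / lrs["lr_neg"].point
        assert dor == pytest.approx(tp * tn / (fn * fp), rel=1e-12)
        # interval log-symmetric around the point
        lo, hi, pt = lrs["lr_pos"].ci_low, lrs["lr_pos"].ci_high, lrs["lr_pos"].point
        assert math.log(hi) - math.log(pt) == pytest.approx(math.log(pt) - math.log(lo), abs=1e-9)

    def test_zero_cell_continuity_correction(self):
        t = Table2x2(10, 0, 5, 20)
        lrs = likelihood_ratios(t)
        assert lrs["lr_pos"].continuity_corrected
        with pytest.raises(ValueError):
            likelihood_ratios(t, strict=True)


class TestInclusiveSensitivity:
    def test_reanalysis_matches_printed_value(self, study_tables):
        est = inclusive_sensitivity(study_tables[ComparisonRule.ANY], n_total=1200, n_evaluable=1087)
        assert round_half_away(est.point, 2) == 0.59

    def test_no_attrition_is_plain_sensitivity(self, study_tables):
        t = study_tables[ComparisonRule.ANY]
        est = inclusive_sensitivity(t, n_total=t.n, n_evaluable=t.n)
        assert est.point == pytest.approx(t.tp / (t.tp + t.fn))

    def test_zero_tp_stays_zero(self):
        assert inclusive_sensitivity(Table2x2(0, 10, 5, 85), 200, 100).point == 0.0

    def test_errors(self, study_tables):
        t = study_tables[ComparisonRule.ANY]
        with pytest.raises(ValueError):
            inclusive_sensitivity(t, n_total=100, n_evaluable=0)
        with pytest.raises(ValueError):
            inclusive_sensitivity(t, n_total=100, n_evaluable=200)


class TestSampleSize:
    def test_planning_values_give_about_one_thousand(self):
        n = sample_size_for_lr(0.9, 0.91, 0.15, exclude_value=8, level=0.95)
        assert 800 <= n <= 1200

    def test_monotone_in_slack(self):
        ns = [sample_size_for_lr(0.9, 0.91, 0.15, e) for e in (2, 4, 6, 8, 9)]
        assert ns == sorted(ns)

    def test_scales_with_inverse_squared_log_slack(self):
        # n ~ z^2 c / log(LR/e)^2: check against the closed-form ratio
        lr = 0.9 / 0.09
        n1 = sample_size_for_lr(0.9, 0.91, 0.15, 5)
        n2 = sample_size_for_lr(0.9, 0.91, 0.15, 8)
        ratio = (math.log(lr / 5) / math.log(lr / 8)) ** 2
        assert n2 / n1 == pytest.approx(ratio, rel=0.01)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sample_size_for_lr(0.9, 0.91, 0.15, exclude_value=11)  # above LR+
        with pytest.raises(ValueError):
            sample_size_for_lr(0.9, 0.91, 0.0, exclude_value=8)
        with pytest.raises(ValueError):
            sample_size_for_lr(1.0, 0.91, 0.15, exclude_value=8)
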