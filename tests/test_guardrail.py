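"""Guardrail: flag statistic, threshold calibration, exact CIs, DeLong AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from fetalqc import guardrail
from fetalqc.errors import CalibrationError, ConfigError, DegenerateEvaluationError


def brute_force_thresholds(stats, labels, targets):
    """Enumerate every candidate cut-point (oracle for calibrate_thresholds)."""
    stats = np.asarray(stats, float)
    labels = np.asarray(labels, bool)
    positives = np.unique(stats[labels])
    out = {}
    for s in targets:
        feasible = [t for t in positives if np.mean(stats[labels] >= t) >= s]
        out[s] = max(feasible)
    return out


def cp_inversion_oracle(k, n, level=0.95, step=1e-5):
    """Clopper-Pearson by brute-force inversion of the binomial CDF."""
    alpha = 1.0 - level
    grid = np.arange(step, 1.0, step)
    lower = 0.0
    if k > 0:
        ok = sps.binom.sf(k - 1, n, grid) <= alpha / 2
        lower = grid[ok].max() if ok.any() else 0.0
    upper = 1.0
    if k < n:
        ok = sps.binom.cdf(k, n, grid) <= alpha / 2
        upper = grid[ok].min() if ok.any() else 1.0
    return lower, upper


class TestFlagStatistic:
    def test_known_values(self):
        assert guardrail.compute_flag_statistic(200.0, 200.0) == 0.0
        assert guardrail.compute_flag_statistic(200.0, 189.4) == pytest.approx(10.6)

    def test_symmetry(self, rng):
        a, b = rng.normal(200, 10, 50), rng.normal(200, 10, 50)
        assert np.array_equal(
            guardrail.compute_flag_statistic(a, b), guardrail.compute_flag_statistic(b, a)
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ConfigError):
            guardrail.compute_flag_statistic(np.nan, 200.0)


class TestCalibrateThresholds:
    def test_enumerated_example(self):
        stats = np.arange(1.0, 11.0)
        labels = np.ones(10, bool)
        got = guardrail.calibrate_thresholds(stats, labels, [0.8])
        assert got[0.8] == 3.0  # 8 of 10 positives have statistic >= 3

    def test_capture_all_uses_minimum_positive(self, rng):
        stats = rng.uniform(0, 20, 100)
        labels = rng.random(100) < 0.4
        got = guardrail.calibrate_thresholds(stats, labels, [1.0])
        assert got[1.0] == stats[labels].min()

    def test_matches_brute_force_on_random_sets(self, rng):
        targets = (0.8, 0.9, 0.95)
        for _ in range(20):
            n = rng.integers(50, 300)
            stats = np.round(rng.gamma(2.0, 4.0, n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.35
            if labels.sum() < 5:
                continue
            got = guardrail.calibrate_thresholds(stats, labels, targets)
            assert got == brute_force_thresholds(stats, labels, targets)

    def test_thresholds_non_increasing_in_target(self, rng):
        stats = rng.gamma(2.0, 4.0, 500)
        labels = rng.random(500) < 0.3
        got = guardrail.calibrate_thresholds(stats, labels, (0.8, 0.9, 0.95))
        assert got[0.8] >= got[0.9] >= got[0.95]

    def test_tightness_next_larger_candidate_violates(self, rng):
        stats = np.round(rng.gamma(2.0, 4.0, 400), 1)
        labels = rng.random(400) < 0.3
        pos = stats[labels]
        got = guardrail.calibrate_thresholds(stats, labels, (0.8, 0.9))
        for target, t in got.items():
            assert np.mean(pos >= t) >= target
            larger = np.unique(pos[pos > t])
            if larger.size:
                assert np.mean(pos >= larger[0]) < target

    def test_no_positives_raises(self):
        with pytest.raises(CalibrationError):
            guardrail.calibrate_thresholds([1.0, 2.0], [False, False], [0.8])


class TestClopperPearson:
    def test_boundary_cases_exact(self):
        assert guardrail.clopper_pearson_ci(0, 10)[0] == 0.0
        assert guardrail.clopper_pearson_ci(10, 10)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(8, 10), (0, 10), (10, 10), (1, 25), (40, 80)])
    def test_matches_cdf_inversion_oracle(self, k, n):
        got = guardrail.clopper_pearson_ci(k, n)
        oracle = cp_inversion_oracle(k, n)
        assert got[0] == pytest.approx(oracle[0], abs=1e-4)
        assert got[1] == pytest.approx(oracle[1], abs=1e-4)

    @pytest.mark.parametrize("k,n", [(8, 10), (3, 17), (55, 120)])
    def test_agrees_with_statsmodels_beta_method(self, k, n):
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert guardrail.clopper_pearson_ci(k, n) == pytest.approx((lo, hi), abs=1e-12)

    def test_coverage_at_least_nominal(self, rng):
        # Exact intervals are conservative: empirical coverage >= 95%.
        for n in (10, 50):
            for p in (0.1, 0.5, 0.9):
                draws = rng.binomial(n, p, 2000)
                lower = np.where(draws == 0, 0.0, sps.beta.ppf(0.025, draws, n - draws + 1))
                upper = np.where(draws == n, 1.0, sps.beta.ppf(0.975, draws + 1, n - draws))
                coverage = np.mean((lower <= p) & (p <= upper))
                assert coverage >= 0.95 - 0.012  # two MC standard errors

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigError):
            guardrail.clopper_pearson_ci(5, 4)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(k=st.integers(0, 80), n=st.integers(1, 80))
    def test_interval_always_brackets_point_estimate(self, k, n):
        k = min(k, n)
        lo, hi = guardrail.clopper_pearson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(k=st.integers(1, 40), n=st.integers(2, 40), wider=st.floats(0.96, 0.999))
    def test_higher_level_gives_wider_interval(self, k, n, wider):
        k = min(k, n)
        lo95, hi95 = guardrail.clopper_pearson_ci(k, n, 0.95)
        lo_w, hi_w = guardrail.clopper_pearson_ci(k, n, wider)
        assert lo_w <= lo95 and hi_w >= hi95


class TestDeLong:
    def test_complete_separation(self):
        stats = np.array([1.0, 2.0] * 5 + [0.0] * 5)
        labels = np.array([True] * 10 + [False] * 5)
        auc, lo, hi = guardrail.delong_auc_ci(stats, labels)
        assert auc == 1.0 and hi == 1.0

    def test_all_tied_gives_half(self):
        stats = np.ones(20)
        labels = np.array([True] * 10 + [False] * 10)
        auc, _, _ = guardrail.delong_auc_ci(stats, labels)
        assert auc == 0.5

    def test_null_auc_near_half(self, rng):
        stats = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        auc, lo, hi = guardrail.delong_auc_ci(stats, labels)
        assert lo < 0.5 < hi and abs(auc - 0.5) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        stats = rng.gamma(2.0, 3.0, 300)
        labels = rng.random(300) < 0.4
        direct = guardrail.delong_auc_ci(stats, labels)
        transformed = guardrail.delong_auc_ci(np.log1p(stats) ** 3, labels)
        assert direct == pytest.approx(transformed)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateEvaluationError):
            guardrail.delong_auc_ci(np.arange(12.0), np.ones(12, bool))


class TestEvaluateGuardrail:
    def _result_from_counts(self, tp, fn, tn, fp):
        # Build statistics that reproduce the requested confusion table at
        # threshold 10: flagged scans get statistic 12, unflagged 5.
        stats = np.r_[np.full(tp + fp, 12.0), np.full(fn + tn, 5.0)]
        labels = np.r_[
            np.ones(tp, bool), np.zeros(fp, bool), np.ones(fn, bool), np.zeros(tn, bool)
        ]
        return guardrail.evaluate_guardrail(stats, labels, 10.0)

    def test_hand_built_confusion_table(self):
        result = self._result_from_counts(tp=81, fn=19, tn=90, fp=10)
        assert (result.tp, result.fn, result.tn, result.fp) == (81, 19, 90, 10)
        assert result.sensitivity[0] == pytest.approx(0.81)
        assert result.specificity[0] == pytest.approx(0.90)
        assert result.sensitivity[1:] == pytest.approx(cp_inversion_oracle(81, 100), abs=1e-4)
        assert result.specificity[1:] == pytest.approx(cp_inversion_oracle(90, 100), abs=1e-4)
        assert result.n == 200

    def test_point_estimates_inside_their_intervals(self, rng):
        stats = rng.gamma(2.0, 4.0, 400)
        labels = stats + rng.normal(0, 4, 400) > 10
        result = guardrail.evaluate_guardrail(stats, labels, 8.0)
        for est, lo, hi in (result.sensitivity, result.specificity, result.ppv, result.npv, result.auc):
            assert lo <= est <= hi

    def test_perfect_separation(self):
        stats = np.r_[np.full(30, 20.0), np.full(30, 1.0)]
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        result = guardrail.evaluate_guardrail(stats, labels, 10.0)
        assert result.sensitivity[0] == 1.0
        assert result.specificity[0] == 1.0
        assert result.auc[0] == 1.0

    def test_sensitivity_specificity_monotone_in_threshold(self, rng):
        stats = rng.gamma(2.0, 4.0, 500)
        labels = stats + rng.normal(0, 3, 500) > 9
        results = [guardrail.evaluate_guardrail(stats, labels, t) for t in (4.0, 8.0, 12.0)]
        sens = [r.sensitivity[0] for r in results]
        spec = [r.specificity[0] for r in results]
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(DegenerateEvaluationError):
            guardrail.evaluate_guardrail(np.arange(20.0), np.ones(20, bool), 5.0)
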