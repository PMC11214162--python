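"""Paired comparison statistics: MAE/RMSE SEs, t-test, McNemar, subsets."""

import numpy as np
import pandas as pd
import pytest

from fetalqc import stats
from fetalqc.errors import ConfigError


def make_table(model_errors, expert_errors, true_ga=None, participants=None):
    n = len(model_errors)
    return pd.DataFrame(
        {
            "abs_error_model": np.asarray(model_errors, float),
            "abs_error_expert": np.asarray(expert_errors, float),
            "true_ga": np.full(n, 150.0) if true_ga is None else np.asarray(true_ga, float),
            "participant_id": np.arange(n) if participants is None else np.asarray(participants),
        }
    )


class TestPointSummaries:
    def test_mae_hand_arithmetic(self):
        assert stats.mae_with_se([3.0, 5.0]) == pytest.approx((4.0, 1.0))

    def test_constant_errors_zero_se(self):
        assert stats.mae_with_se([2.0] * 10)[1] == 0.0

    def test_mae_matches_manual_computation(self, rng):
        values = rng.gamma(2.0, 2.0, 10)
        mean = sum(values) / 10
        sd = (sum((v - mean) ** 2 for v in values) / 9) ** 0.5
        assert stats.mae_with_se(values) == pytest.approx((mean, sd / 10**0.5))

    def test_mae_never_exceeds_rmse(self, rng):
        for _ in range(20):
            values = rng.gamma(2.0, 2.0, 50)
            assert stats.mae_with_se(values)[0] <= stats.rmse_with_se(values)[0] + 1e-12

    def test_rmse_se_by_delta_method(self, rng):
        values = rng.gamma(2.0, 2.0, 200)
        squares = values**2
        rmse = np.sqrt(squares.mean())
        expected_se = squares.std(ddof=1) / np.sqrt(200) / (2 * rmse)
        assert stats.rmse_with_se(values) == pytest.approx((rmse, expected_se))

    def test_too_few_values_rejected(self):
        with pytest.raises(ConfigError):
            stats.mae_with_se([1.0])


class TestPairedComparison:
    def test_identical_columns_degenerate_with_p_one(self, rng):
        errors = rng.gamma(2.0, 2.0, 30)
        result = stats.paired_mae_comparison(make_table(errors, errors))
        assert result.difference == 0.0 and result.p_value == 1.0 and result.degenerate

    def test_exact_shift_degenerate(self, rng):
        errors = rng.gamma(2.0, 2.0, 30)
        result = stats.paired_mae_comparison(make_table(errors, errors + 1.0))
        assert result.difference == pytest.approx(-1.0)
        assert result.degenerate and result.ci == pytest.approx((-1.0, -1.0))

    def test_ci_covers_true_shift(self, rng):
        covered = 0
        for _ in range(200):
            base = rng.gamma(2.0, 2.0, 1000)
            model = base + rng.normal(-0.9, 2.0, 1000)
            result = stats.paired_mae_comparison(make_table(model, base))
            covered += result.ci[0] <= -0.9 <= result.ci[1]
        assert covered >= 0.93 * 200  # nominal 95%, small-sample slack

    def test_matches_scipy_p_value(self, rng):
        table = make_table(rng.gamma(2, 2, 50), rng.gamma(2, 2, 50))
        from scipy.stats import ttest_rel

        expected = ttest_rel(table["abs_error_model"], table["abs_error_expert"]).pvalue
        assert stats.paired_mae_comparison(table).p_value == pytest.approx(expected)


class TestProportionWithin:
    def test_all_within_both(self):
        table = make_table(np.full(20, 2.0), np.full(20, 3.0))
        result = stats.proportion_within(table)
        assert (result.p_model, result.p_expert, result.difference) == (1.0, 1.0, 0.0)
        assert result.degenerate

    def test_mcnemar_corrected_chi_square_hand_formula(self):
        # Discordant cells b=20, c=5: corrected statistic (|b-c|-1)^2/(b+c).
        model = np.r_[np.full(20, 5.0), np.full(5, 15.0), np.full(30, 5.0)]
        expert = np.r_[np.full(20, 15.0), np.full(5, 5.0), np.full(30, 5.0)]
        result = stats.proportion_within(make_table(model, expert))
        assert result.discordant == (20, 5)
        assert result.method == "chi2_corrected"
        from scipy.stats import chi2

        expected_p = chi2.sf((abs(20 - 5) - 1) ** 2 / 25, 1)
        assert result.mcnemar_p == pytest.approx(expected_p)

    def test_exact_method_below_discordant_threshold(self):
        model = np.r_[np.full(6, 5.0), np.full(2, 15.0), np.full(30, 5.0)]
        expert = np.r_[np.full(6, 15.0), np.full(2, 5.0), np.full(30, 5.0)]
        result = stats.proportion_within(make_table(model, expert))
        assert result.method == "exact"
        from scipy.stats import binomtest

        assert result.mcnemar_p == pytest.approx(binomtest(2, 8, 0.5).pvalue)

    def test_cdf_at_cutoff_equals_proportion(self, rng):
        errors_m = rng.gamma(2.0, 3.0, 500)
        errors_e = rng.gamma(2.0, 3.0, 500)
        result = stats.proportion_within(make_table(errors_m, errors_e), cutoff_days=10.0)
        assert result.p_model == np.mean(errors_m < 10.0)  # strict inequality

    def test_directional_agreement_ci_vs_p(self, rng):
        # CI excluding 0 should almost always coincide with p < 0.05.
        agree = total = 0
        for _ in range(200):
            m = rng.gamma(2.0, 3.0, 1000)
            e = rng.gamma(2.2, 3.0, 1000)
            result = stats.proportion_within(make_table(m, e))
            if result.degenerate:
                continue
            excludes = not (result.wald_ci[0] <= 0.0 <= result.wald_ci[1])
            agree += excludes == (result.mcnemar_p < 0.05)
            total += 1
        assert agree >= 0.95 * total


class TestTrimesterSubsets:
    def test_boundary_scan_is_third_trimester(self):
        table = make_table([1, 2, 3], [1, 2, 3], true_ga=[150.0, 196.0, 250.0])
        subsets = stats.trimester_subsets(table, 196.0)
        assert len(subsets["second"]) == 1 and len(subsets["third"]) == 2

    def test_empty_subset_absent_not_error(self):
        table = make_table([1, 2, 3], [1, 2, 3], true_ga=[150.0, 150.0, 150.0])
        subsets = stats.trimester_subsets(table)
        assert "third" not in subsets and len(subsets["second"]) == 3

    def test_pooled_mae_is_weighted_mean_of_subsets(self, rng):
        table = make_table(
            rng.gamma(2, 2, 100), rng.gamma(2, 2, 100), true_ga=rng.uniform(98, 280, 100)
        )
        subsets = stats.trimester_subsets(table)
        pooled = stats.mae_with_se(table["abs_error_model"])[0]
        weighted = sum(
            len(s) * stats.mae_with_se(s["abs_error_model"])[0] for s in subsets.values()
        ) / len(table)
        assert pooled == pytest.approx(weighted)

    def test_invalid_boundary_rejected(self):
        with pytest.raises(ConfigError):
            stats.trimester_subsets(make_table([1, 2, 3], [1, 2, 3]), 300.0)


class TestOneScanPerParticipant:
    def test_cardinality_and_single_scan_kept(self, rng):
        table = make_table(
            rng.gamma(2, 2, 7), rng.gamma(2, 2, 7), participants=[0, 0, 0, 1, 1, 2, 3]
        )
        out = stats.one_scan_per_participant(table, seed=4)
        assert len(out) == 4
        assert set(out["participant_id"]) == {0, 1, 2, 3}
        assert (out[out["participant_id"] == 3].index == [6]).all()

    def test_selection_uniform_over_seeds(self):
        table = make_table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], participants=[7, 7, 7])
        counts = np.zeros(3)
        for seed in range(3000):
            out = stats.one_scan_per_participant(table, seed=seed)
            counts[out.index[0]] += 1
        freq = counts / 3000
        assert np.all(np.abs(freq - 1 / 3) < 0.03)


class TestComparisonReport:
    def test_report_internally_consistent(self, default_cohort):
        table = stats.paired_error_table(default_cohort)
        report = stats.comparison_report(table)
        assert report.n == len(table)
        assert report.mae_comparison.difference == pytest.approx(
            report.mae_model[0] - report.mae_expert[0]
        )
        ci = report.mae_comparison.ci
        assert ci[0] <= report.mae_comparison.difference <= ci[1]
        assert set(report.trimesters) == {"second", "third"}
        d = report.to_dict()
        assert d["within_cutoff"]["p_model"] == report.within_cutoff.p_model
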