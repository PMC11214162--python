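"""Paired accuracy comparison of the model and expert-biometry GA estimates.

All statistics operate on a paired error table: one row per scan with the
absolute error of each estimator against ground truth.  The machinery
mirrors a standard accuracy-comparison layout: MAE and RMSE with standard
errors, the paired-t difference with its interval, trimester subsets, the
proportion of scans within a day cutoff compared by McNemar's test with a
Wald interval for the paired difference in proportions.

Conventions (documented because the source wordings are loose):

* SE of the MAE is the sample SD of absolute errors over sqrt(n); SE of
  the RMSE comes from the delta method on the mean squared error.
* "within 10 days" uses strict ``<``.
* McNemar switches from the exact binomial test to the continuity-
  corrected chi-square at 25 discordant pairs (configurable).
* The trimester boundary defaults to 196 days (second trimester 98-195,
  third 196 and above) and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ConfigError, DegenerateTestError

REQUIRED_COLUMNS = ("abs_error_model", "abs_error_expert", "true_ga", "participant_id")


def paired_error_table(scans: pd.DataFrame) -> pd.DataFrame:
    """Build the paired error table from a scan table."""
    return pd.DataFrame(
        {
            "abs_error_model": np.abs(scans["model_ga"] - scans["true_ga"]),
            "abs_error_expert": np.abs(scans["expert_ga"] - scans["true_ga"]),
            "true_ga": scans["true_ga"].to_numpy(),
            "participant_id": scans["participant_id"].to_numpy(),
        }
    )


def mae_with_se(abs_errors) -> tuple[float, float]:
    """Mean absolute error and its standard error (sample SD / sqrt(n))."""
    errors = np.asarray(abs_errors, dtype=float)
    if errors.size < 2:
        raise ConfigError("need at least 2 errors for a standard error")
    return float(errors.mean()), float(errors.std(ddof=1) / np.sqrt(errors.size))


def rmse_with_se(abs_errors) -> tuple[float, float]:
    """RMSE and its delta-method standard error.

    With s = mean squared error, RMSE = sqrt(s) and
    SE(RMSE) = SE(s) / (2 sqrt(s)).
    """
    errors = np.asarray(abs_errors, dtype=float)
    if errors.size < 2:
        raise ConfigError("need at least 2 errors for a standard error")
    squares = errors**2
    rmse = float(np.sqrt(squares.mean()))
    if rmse == 0.0:
        return 0.0, 0.0
    se_mean_square = squares.std(ddof=1) / np.sqrt(squares.size)
    return rmse, float(se_mean_square / (2.0 * rmse))


@dataclass(frozen=True)
class PairedComparison:
    difference: float
    ci: tuple[float, float]
    p_value: float
    degenerate: bool = False


def paired_mae_comparison(table: pd.DataFrame, level: float = 0.95) -> PairedComparison:
    """Paired t-test and CI for the model-minus-expert MAE difference."""
    d = (table["abs_error_model"] - table["abs_error_expert"]).to_numpy(dtype=float)
    if d.size < 3:
        raise ConfigError("need at least 3 pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd <= 1e-10 * (abs(mean) + 1.0):
        # All per-scan differences (numerically) identical: t is undefined.
        return PairedComparison(mean, (mean, mean), 1.0 if mean == 0.0 else 0.0, degenerate=True)
    t_res = sps.ttest_rel(table["abs_error_model"], table["abs_error_expert"])
    half = sps.t.ppf(0.5 + level / 2.0, d.size - 1) * sd / np.sqrt(d.size)
    return PairedComparison(mean, (mean - half, mean + half), float(t_res.pvalue))


def paired_rmse_comparison(table: pd.DataFrame, level: float = 0.95) -> PairedComparison:
    """Delta-method CI for the paired RMSE difference.

    The difference of RMSEs is a smooth function of the two mean squared
    errors; its variance follows from the per-scan influence values
    ``e_m^2 / (2 rmse_m) - e_e^2 / (2 rmse_e)``, which respect the pairing.
    """
    em = table["abs_error_model"].to_numpy(dtype=float)
    ee = table["abs_error_expert"].to_numpy(dtype=float)
    if em.size < 3:
        raise ConfigError("need at least 3 pairs")
    rmse_m, rmse_e = float(np.sqrt(np.mean(em**2))), float(np.sqrt(np.mean(ee**2)))
    if rmse_m == 0.0 or rmse_e == 0.0:
        diff = rmse_m - rmse_e
        return PairedComparison(diff, (diff, diff), 1.0 if diff == 0.0 else 0.0, degenerate=True)
    influence = em**2 / (2.0 * rmse_m) - ee**2 / (2.0 * rmse_e)
    diff = rmse_m - rmse_e
    se = float(influence.std(ddof=1) / np.sqrt(influence.size))
    if se == 0.0:
        return PairedComparison(diff, (diff, diff), 1.0 if diff == 0.0 else 0.0, degenerate=True)
    z = sps.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * float(sps.norm.sf(abs(diff) / se))
    return PairedComparison(diff, (diff - z * se, diff + z * se), p)


@dataclass(frozen=True)
class ProportionComparison:
    """Within-cutoff proportions for both estimators, compared head to head."""

    cutoff_days: float
    p_model: float
    p_expert: float
    se_model: float
    se_expert: float
    difference: float
    wald_ci: tuple[float, float]
    mcnemar_p: float
    discordant: tuple[int, int]  # (model only within, expert only within)
    method: str
    degenerate: bool = False


def proportion_within(
    table: pd.DataFrame,
    cutoff_days: float = 10.0,
    level: float = 0.95,
    exact_threshold: int = 25,
) -> ProportionComparison:
    """Proportion of scans with absolute error strictly below the cutoff.

    The two estimators are compared on the same scans: McNemar's test on
    the discordant pairs (exact binomial when there are fewer than
    ``exact_threshold`` discordant pairs, otherwise the continuity-
    corrected chi-square) and a paired Wald interval for the difference in
    proportions.
    """
    if len(table) < 10:
        raise ConfigError("need at least 10 pairs")
    within_m = (table["abs_error_model"] < cutoff_days).to_numpy()
    within_e = (table["abs_error_expert"] < cutoff_days).to_numpy()
    n = within_m.size
    p_m, p_e = float(within_m.mean()), float(within_e.mean())
    se_m = float(np.sqrt(p_m * (1 - p_m) / n))
    se_e = float(np.sqrt(p_e * (1 - p_e) / n))
    b = int(np.sum(within_m & ~within_e))  # model within, expert not
    c = int(np.sum(~within_m & within_e))
    diff = p_m - p_e
    if b + c == 0:
        return ProportionComparison(
            cutoff_days, p_m, p_e, se_m, se_e, diff, (diff, diff),
            float("nan"), (b, c), "degenerate", degenerate=True,
        )
    exact = (b + c) < exact_threshold
    table2x2 = [[int(np.sum(within_m & within_e)), b], [c, int(np.sum(~within_m & ~within_e))]]
    result = _sm_mcnemar(table2x2, exact=exact, correction=True)
    se_diff = float(np.sqrt(b + c - (b - c) ** 2 / n) / n)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return ProportionComparison(
        cutoff_days, p_m, p_e, se_m, se_e, diff,
        (diff - z * se_diff, diff + z * se_diff),
        float(result.pvalue), (b, c), "exact" if exact else "chi2_corrected",
    )


def trimester_subsets(table: pd.DataFrame, boundary_days: float = 196.0) -> dict[str, pd.DataFrame]:
    """Partition the paired table at the trimester boundary.

    Scans at exactly the boundary fall in the third trimester.  Empty
    subsets are simply absent from the result rather than raised.
    """
    if not 98.0 < boundary_days < 280.0:
        raise ConfigError("trimester boundary must lie in (98, 280) days")
    third = table["true_ga"].to_numpy() >= boundary_days
    out = {}
    if (~third).any():
        out["second"] = table.loc[~third]
    if third.any():
        out["third"] = table.loc[third]
    return out


def one_scan_per_participant(
    table: pd.DataFrame, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Keep one uniformly chosen row per participant (seeded)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    order = rng.permutation(len(table))
    shuffled = table.iloc[order]
    return shuffled.groupby("participant_id", sort=True).head(1).sort_index()


@dataclass(frozen=True)
class ComparisonReport:
    """Accuracy-comparison block: the full paired analysis of one test set."""

    n: int
    mae_model: tuple[float, float]
    mae_expert: tuple[float, float]
    mae_comparison: PairedComparison
    rmse_model: tuple[float, float]
    rmse_expert: tuple[float, float]
    rmse_comparison: PairedComparison
    trimesters: dict
    within_cutoff: ProportionComparison
    trimester_boundary_days: float

    def to_dict(self) -> dict:
        def pair(t):
            return {"estimate": t[0], "se": t[1]}

        def comparison(c: PairedComparison):
            return {
                "difference": c.difference,
                "ci_lower": c.ci[0],
                "ci_upper": c.ci[1],
                "p_value": c.p_value,
                "degenerate": c.degenerate,
            }

        return {
            "n": self.n,
            "mae_model": pair(self.mae_model),
            "mae_expert": pair(self.mae_expert),
            "mae_comparison": comparison(self.mae_comparison),
            "rmse_model": pair(self.rmse_model),
            "rmse_expert": pair(self.rmse_expert),
            "rmse_comparison": comparison(self.rmse_comparison),
            "trimester_boundary_days": self.trimester_boundary_days,
            "trimesters": {
                name: {
                    "n": block["n"],
                    "mae_model": pair(block["mae_model"]),
                    "mae_expert": pair(block["mae_expert"]),
                    "mae_comparison": comparison(block["mae_comparison"]),
                }
                for name, block in self.trimesters.items()
            },
            "within_cutoff": {
                "cutoff_days": self.within_cutoff.cutoff_days,
                "p_model": self.within_cutoff.p_model,
                "p_expert": self.within_cutoff.p_expert,
                "se_model": self.within_cutoff.se_model,
                "se_expert": self.within_cutoff.se_expert,
                "difference": self.within_cutoff.difference,
                "wald_ci_lower": self.within_cutoff.wald_ci[0],
                "wald_ci_upper": self.within_cutoff.wald_ci[1],
                "mcnemar_p": self.within_cutoff.mcnemar_p,
                "mcnemar_method": self.within_cutoff.method,
            },
        }


def comparison_report(
    table: pd.DataFrame,
    level: float = 0.95,
    cutoff_days: float = 10.0,
    trimester_boundary_days: float = 196.0,
) -> ComparisonReport:
    """Full paired accuracy comparison on one paired error table."""
    trimester_blocks = {}
    for name, subset in trimester_subsets(table, trimester_boundary_days).items():
        if len(subset) < 3:
            continue
        trimester_blocks[name] = {
            "n": len(subset),
            "mae_model": mae_with_se(subset["abs_error_model"]),
            "mae_expert": mae_with_se(subset["abs_error_expert"]),
            "mae_comparison": paired_mae_comparison(subset, level),
        }
    return ComparisonReport(
        n=len(table),
        mae_model=mae_with_se(table["abs_error_model"]),
        mae_expert=mae_with_se(table["abs_error_expert"]),
        mae_comparison=paired_mae_comparison(table, level),
        rmse_model=rmse_with_se(table["abs_error_model"]),
        rmse_expert=rmse_with_se(table["abs_error_expert"]),
        rmse_comparison=paired_rmse_comparison(table, level),
        trimesters=trimester_blocks,
        within_cutoff=proportion_within(table, cutoff_days, level),
        trimester_boundary_days=trimester_boundary_days,
    )
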