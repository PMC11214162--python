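"""Guardrail calibration and evaluation.

The guardrail flags a scan when the discrepancy between the AI model's GA
estimate and the operator's biometry-derived GA, in days, is at least a
threshold: flag iff ``|model GA - novice GA| >= t``.  Thresholds are
calibrated on the tuning split to capture a target fraction of gross
errors (80/90/95%), then evaluated once on the held-out test split with
exact (Clopper-Pearson) intervals for the four operating characteristics
and a DeLong interval for the AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps

from .errors import CalibrationError, ConfigError, DegenerateEvaluationError


def compute_flag_statistic(model_ga, novice_ga):
    """Absolute model-operator GA discrepancy in days (vectorised)."""
    model_ga = np.asarray(model_ga, dtype=float)
    novice_ga = np.asarray(novice_ga, dtype=float)
    if not (np.all(np.isfinite(model_ga)) and np.all(np.isfinite(novice_ga))):
        raise ConfigError("GA estimates must be finite")
    out = np.abs(model_ga - novice_ga)
    return float(out) if out.ndim == 0 else out


def calibrate_thresholds(
    flag_statistics,
    gross_error,
    target_sensitivities: Iterable[float],
    *,
    min_positives: int = 1,
) -> dict[float, float]:
    """Tuning-set cut-points achieving each target sensitivity.

    For target s the threshold is the LARGEST candidate t such that the
    fraction of gross-error scans with statistic >= t is at least s;
    candidates are the observed statistics of the positive scans, making
    the ROC an explicit step function (no interpolation).  Equivalently,
    with m positives sorted descending, t is the ceil(s*m)-th largest
    positive statistic.  Thresholds are therefore non-increasing in s.
    """
    stats = np.asarray(flag_statistics, dtype=float)
    labels = np.asarray(gross_error, dtype=bool)
    if stats.shape != labels.shape:
        raise ConfigError("flag statistics and labels must align")
    positives = np.sort(stats[labels])[::-1]
    if positives.size < max(min_positives, 1):
        raise CalibrationError(
            f"tuning set has {positives.size} gross-error positives; "
            f"at least {max(min_positives, 1)} required for threshold calibration"
        )
    out: dict[float, float] = {}
    for target in target_sensitivities:
        if not 0.0 < target <= 1.0:
            raise ConfigError(f"target sensitivity {target} must be in (0, 1]")
        k = int(np.ceil(target * positives.size - 1e-12))
        out[float(target)] = float(positives[k - 1])
    return out


def clopper_pearson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta-distribution quantiles.

    The lower bound is exactly 0 when no successes are observed and the
    upper bound exactly 1 when all trials succeed.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ConfigError(f"invalid counts: {successes}/{trials}")
    if not 0.0 < level < 1.0:
        raise ConfigError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(sps.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lower, upper


def delong_auc_ci(statistics, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong confidence interval.

    The AUC is the Mann-Whitney statistic with ties counted one half; its
    variance comes from the empirical variances of the DeLong structural
    components (per-positive and per-negative placement values).  The
    interval is formed on the AUC scale and clipped to [0, 1]; under
    complete separation the variance collapses to zero and the interval
    degenerates to the point estimate.
    """
    stats = np.asarray(statistics, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if stats.shape != y.shape:
        raise ConfigError("statistics and labels must align")
    if stats.size < 10:
        raise ConfigError("DeLong inference needs at least 10 observations")
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise DegenerateEvaluationError("both classes required for AUC")
    x_pos, x_neg = stats[y], stats[~y]
    rank_all = sps.rankdata(np.concatenate([x_pos, x_neg]))
    rank_pos = sps.rankdata(x_pos)
    rank_neg = sps.rankdata(x_neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n        # placement of each positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # placement of each negative
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = sps.norm.ppf(0.5 + level / 2.0) * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


@dataclass(frozen=True)
class GuardrailResult:
    """Operating characteristics of one calibrated cut-point on the test set."""

    threshold_days: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: tuple[float, float, float]  # (estimate, lower, upper)
    specificity: tuple[float, float, float]
    ppv: tuple[float, float, float]
    npv: tuple[float, float, float]
    auc: tuple[float, float, float]
    level: float = 0.95

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "threshold_days": self.threshold_days,
            "n": self.n,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            **{
                name: {"estimate": est, "lower": lo, "upper": hi}
                for name, (est, lo, hi) in (
                    ("sensitivity", self.sensitivity),
                    ("specificity", self.specificity),
                    ("ppv", self.ppv),
                    ("npv", self.npv),
                    ("auc", self.auc),
                )
            },
            "level": self.level,
        }


def _proportion_with_ci(successes: int, trials: int, level: float) -> tuple[float, float, float]:
    lower, upper = clopper_pearson_ci(successes, trials, level)
    return successes / trials, lower, upper


def evaluate_guardrail(flag_statistics, gross_error, threshold_days: float, level: float = 0.95) -> GuardrailResult:
    """Test-set confusion counts and interval estimates at one cut-point.

    Flags scans with statistic >= threshold; reports sensitivity,
    specificity, PPV and NPV with exact Clopper-Pearson intervals and the
    AUC of the flag statistic with its DeLong interval.
    """
    stats = np.asarray(flag_statistics, dtype=float)
    labels = np.asarray(gross_error, dtype=bool)
    if stats.shape != labels.shape:
        raise ConfigError("flag statistics and labels must align")
    if labels.all() or not labels.any():
        raise DegenerateEvaluationError(
            "test set must contain both gross-error and clean scans"
        )
    flagged = stats >= threshold_days
    tp = int(np.sum(flagged & labels))
    fp = int(np.sum(flagged & ~labels))
    fn = int(np.sum(~flagged & labels))
    tn = int(np.sum(~flagged & ~labels))
    if min(tp + fn, tn + fp) == 0 or min(tp + fp, tn + fn) < 0:  # pragma: no cover
        raise DegenerateEvaluationError("degenerate confusion table")
    ppv = _proportion_with_ci(tp, tp + fp, level) if tp + fp > 0 else (float("nan"),) * 3
    npv = _proportion_with_ci(tn, tn + fn, level) if tn + fn > 0 else (float("nan"),) * 3
    return GuardrailResult(
        threshold_days=float(threshold_days),
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_proportion_with_ci(tp, tp + fn, level),
        specificity=_proportion_with_ci(tn, tn + fp, level),
        ppv=ppv,
        npv=npv,
        auc=delong_auc_ci(stats, labels, level),
        level=level,
    )
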