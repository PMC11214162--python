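"""Synthetic study cohorts with a calibrated error structure.

The generator emulates a second/third-trimester ultrasound cohort: each
participant contributes one or more scans; each scan has a true gestational
age (GA), expert biometry, an expert (biometry-formula) GA estimate and an
AI-model GA estimate.  Three error sources are modelled:

* a *shared dating error* per pregnancy -- ground truth itself is an
  estimate (a prior dating scan), so every estimate for one pregnancy is
  off by a common Gaussian amount; this is also what induces correlation
  between model and expert errors;
* *expert measurement error* -- multiplicative lognormal noise per
  structure, reflecting the 3-6% inter-observer variability reported for
  expert sonographers;
* *model error* -- an independent zero-mean Gaussian scale mixture.

Calibration works on published accuracy moments: the model-error mixture is
solved in closed form so that the TOTAL model error (shared + independent)
reproduces a target (MAE, RMSE) pair, and the expert per-structure CV is
found by monotone search so the simulated expert GA error RMSE matches its
target.  A single Gaussian cannot match the published pair (its MAE/RMSE
ratio is pinned at sqrt(2/pi) ~ 0.798, above the observed 3.87/5.01 =
0.772), hence the two-component mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import formulas
from .errors import ConfigError, InfeasibleCalibrationError, SplitError
from .formulas import FormulaSpec

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

#: Per-structure expert CV calibrated with ``calibrate_expert_cv`` under the
#: default settings (expert GA RMSE 6.47 days, shared dating SD 2.5 days,
#: Intergrowth-21st formula, default GA distribution).  Frozen so default
#: cohorts do not re-run the search; within the reported 3-6% expert
#: inter-observer range.
DEFAULT_EXPERT_CV = 0.0433

#: Published accuracy moments used for the default calibration (days).
DEFAULT_MODEL_MAE, DEFAULT_MODEL_RMSE = 3.87, 5.01
DEFAULT_EXPERT_RMSE = 6.47


@dataclass(frozen=True)
class ScaleMixture:
    """Zero-mean Gaussian scale mixture: weights over component SDs (days)."""

    weights: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.sds) or not self.weights:
            raise ConfigError("mixture weights and sds must be non-empty and equal length")
        if any(w <= 0 for w in self.weights) or abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError("mixture weights must be positive and sum to 1")
        if any(s < 0 for s in self.sds):
            raise ConfigError("mixture sds must be non-negative")

    def mae(self) -> float:
        """E|X| = sqrt(2/pi) * sum_k w_k sigma_k."""
        return _SQRT_2_OVER_PI * float(np.dot(self.weights, self.sds))

    def rmse(self) -> float:
        """sqrt(E[X^2]) = sqrt(sum_k w_k sigma_k^2)."""
        return float(np.sqrt(np.dot(self.weights, np.square(self.sds))))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        component = rng.choice(len(self.weights), size=size, p=self.weights)
        return rng.standard_normal(size) * np.asarray(self.sds)[component]


def calibrate_scale_mixture(target_mae: float, target_rmse: float) -> ScaleMixture:
    """Solve a two-component zero-mean Gaussian mixture for (MAE, RMSE).

    With weight w on sigma1, the moment equations are
    ``sqrt(2/pi) (w s1 + (1-w) s2) = MAE`` and
    ``w s1^2 + (1-w) s2^2 = RMSE^2``.  Fixing w = 0.8 reduces them to a
    quadratic in s2 with discriminant proportional to
    ``RMSE^2 - (pi/2) MAE^2``, so a solution exists exactly when the target
    tails are at least as heavy as Gaussian.  If the minority component's
    non-negativity constraint fails at w = 0.8 (extremely heavy tails), w
    is pushed along a fixed grid toward 1.
    """
    if not 0 < target_mae <= target_rmse:
        raise InfeasibleCalibrationError(
            f"need 0 < MAE <= RMSE, got MAE={target_mae}, RMSE={target_rmse}"
        )
    m = target_mae / _SQRT_2_OVER_PI  # required mean component SD
    v = target_rmse**2
    if m > target_rmse * (1.0 + 1e-12):
        raise InfeasibleCalibrationError(
            f"MAE/RMSE = {target_mae / target_rmse:.4f} exceeds sqrt(2/pi); "
            "lighter-than-Gaussian tails cannot be represented by a Gaussian scale mixture"
        )
    if m >= target_rmse * (1.0 - 1e-9):  # Gaussian moment identity holds
        return ScaleMixture(weights=(1.0,), sds=(target_rmse,))
    for w in (0.8, 0.9, 0.95, 0.98, 0.99, 0.995, 0.999):
        s2 = m + math.sqrt(w * (v - m * m) / (1.0 - w))
        s1 = (m - (1.0 - w) * s2) / w
        if s1 >= 0:
            mixture = ScaleMixture(weights=(w, 1.0 - w), sds=(s1, s2))
            assert abs(mixture.mae() - target_mae) <= 1e-6 * target_mae
            assert abs(mixture.rmse() - target_rmse) <= 1e-6 * target_rmse
            return mixture
    raise InfeasibleCalibrationError(  # pragma: no cover - grid reaches w=0.999
        f"no feasible mixture for MAE={target_mae}, RMSE={target_rmse}"
    )


def decompose_shared(total: ScaleMixture, shared_sd: float) -> ScaleMixture:
    """Split a total-error mixture into its model-independent part.

    A Gaussian shared term of SD s folds into each mixture component in
    quadrature, so the independent component SDs are sqrt(sigma_k^2 - s^2).
    """
    if shared_sd < 0:
        raise ConfigError("shared_sd must be non-negative")
    if shared_sd > min(total.sds) + 1e-12:
        raise InfeasibleCalibrationError(
            f"shared dating SD {shared_sd} exceeds the smallest total-error "
            f"component SD {min(total.sds):.3f}; reduce shared_dating_sd"
        )
    sds = tuple(math.sqrt(max(s * s - shared_sd * shared_sd, 0.0)) for s in total.sds)
    return ScaleMixture(weights=total.weights, sds=sds)


@dataclass(frozen=True)
class GADistribution:
    """Two-block uniform mixture over GA in days.

    The default puts 55% of scans in the second trimester (98-195 days) and
    45% in the third (196-280 days), reflecting late presentation for care.
    """

    p_second: float = 0.55
    second: tuple[float, float] = (98.0, 195.0)
    third: tuple[float, float] = (196.0, 280.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_second <= 1.0:
            raise ConfigError("p_second must be a proportion")
        for lo, hi in (self.second, self.third):
            if not lo < hi:
                raise ConfigError("GA blocks must have lo < hi")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        take_second = rng.random(size) < self.p_second
        ga = np.where(
            take_second,
            rng.uniform(*self.second, size=size),
            rng.uniform(*self.third, size=size),
        )
        return ga


@dataclass(frozen=True)
class ErrorModel:
    """Error structure of one synthetic cohort.

    ``model_mixture`` is the TOTAL model-error mixture (shared + independent
    parts combined); the generator subtracts ``shared_dating_sd`` in
    quadrature when drawing the independent part, so cohort-level model
    error reproduces the mixture's calibrated moments.
    """

    shared_dating_sd: float = 2.5
    model_mixture: ScaleMixture = field(
        default_factory=lambda: calibrate_scale_mixture(DEFAULT_MODEL_MAE, DEFAULT_MODEL_RMSE)
    )
    expert_cv: float = DEFAULT_EXPERT_CV

    def __post_init__(self) -> None:
        if self.shared_dating_sd < 0:
            raise ConfigError("shared_dating_sd must be non-negative")
        if not 0.0 <= self.expert_cv <= 0.2:
            raise ConfigError("expert_cv must lie in [0, 0.2]")

    @classmethod
    def noiseless(cls) -> "ErrorModel":
        return cls(shared_dating_sd=0.0, model_mixture=ScaleMixture((1.0,), (0.0,)), expert_cv=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate (and later split) one cohort."""

    n_participants: int = 5000
    ga_distribution: GADistribution = field(default_factory=GADistribution)
    visit_rate: float = 0.5  # visits per participant = 1 + Poisson(rate)
    max_visits: int = 8
    error_model: ErrorModel = field(default_factory=ErrorModel)
    formula_name: str = "intergrowth21"
    test_fraction: float = 0.20
    train_tune_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if self.visit_rate < 0 or self.max_visits < 1:
            raise ConfigError("invalid visit model")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.train_tune_ratio <= 0:
            raise ConfigError("train_tune_ratio must be positive")


#: Column schema of the scan table produced by :func:`generate_cohort`.
SCAN_COLUMNS = (
    "participant_id", "visit_index", "true_ga", "bpd", "hc", "ac", "fl",
    "expert_ga", "model_ga", "shared_err", "model_indep_err",
)


def generate_cohort(config: CohortConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Generate one synthetic cohort as a scan table (one row per visit).

    Per scan: true GA is drawn from the configured distribution; expert
    biometry is the formula-consistent median fetus at that GA with
    independent lognormal measurement noise per structure; the expert GA is
    the dating formula applied to that noisy biometry plus the pregnancy's
    shared dating error; the model GA is the true GA plus the shared error
    plus an independent scale-mixture draw.  Reproducible given the config
    seed (or an explicit generator).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    spec = formulas.get_formula(config.formula_name)
    em = config.error_model

    n_visits = 1 + rng.poisson(config.visit_rate, size=config.n_participants)
    n_visits = np.minimum(n_visits, config.max_visits)
    participant = np.repeat(np.arange(config.n_participants), n_visits)
    visit_index = np.concatenate([np.arange(k) for k in n_visits])
    n_scans = participant.size

    shared_by_participant = rng.normal(0.0, em.shared_dating_sd, size=config.n_participants)
    shared = shared_by_participant[participant]

    true_ga = config.ga_distribution.sample(rng, n_scans)
    median = formulas.invert_formula_array(true_ga, spec)
    noise = np.exp(rng.normal(0.0, em.expert_cv, size=(n_scans, 4))) if em.expert_cv > 0 else np.ones((n_scans, 4))
    measured = {m: median[m] * noise[:, j] for j, m in enumerate(("bpd", "hc", "ac", "fl"))}
    # Validity ranges are treated as soft here: the noisy values are genuine
    # observations of an in-range fetus, so they are dated, not rejected.
    expert_formula_ga = formulas._evaluate_terms(spec, measured)
    expert_ga = expert_formula_ga + shared

    indep = decompose_shared(em.model_mixture, em.shared_dating_sd)
    model_indep_err = indep.sample(rng, n_scans)
    model_ga = true_ga + shared + model_indep_err

    return pd.DataFrame(
        {
            "participant_id": participant,
            "visit_index": visit_index,
            "true_ga": true_ga,
            **measured,
            "expert_ga": expert_ga,
            "model_ga": model_ga,
            "shared_err": shared,
            "model_indep_err": model_indep_err,
        }
    )


def calibrate_expert_cv(
    target_expert_rmse: float,
    spec: FormulaSpec,
    ga_distribution: Optional[GADistribution] = None,
    *,
    shared_sd: float = 2.5,
    cv_max: float = 0.2,
    n_sim: int = 20000,
    inner_seed: int = 20180914,
    rel_tol: float = 0.02,
) -> float:
    """Per-structure CV whose simulated expert GA error RMSE hits a target.

    A relative CV propagates through the nonlinear dating formula, so the
    match is made at the GA level: with fixed inner-seed draws (common
    random numbers, making the objective smooth and monotone in cv), the
    expert GA error RMSE -- including the shared dating component -- is
    bisected onto ``target_expert_rmse`` to within ``rel_tol``.
    """
    if target_expert_rmse < 0:
        raise InfeasibleCalibrationError("target RMSE must be non-negative")
    ga_distribution = ga_distribution or GADistribution()
    rng = np.random.default_rng(inner_seed)
    true_ga = ga_distribution.sample(rng, n_sim)
    median = formulas.invert_formula_array(true_ga, spec)
    z = rng.standard_normal((n_sim, 4))
    z_shared = rng.standard_normal(n_sim)

    def simulated_rmse(cv: float) -> float:
        measured = {
            m: median[m] * np.exp(cv * z[:, j]) for j, m in enumerate(("bpd", "hc", "ac", "fl"))
        }
        ga = formulas._evaluate_terms(spec, measured)
        err = ga + shared_sd * z_shared - true_ga
        return float(np.sqrt(np.mean(err**2)))

    if target_expert_rmse == 0.0:
        if shared_sd > 0:
            raise InfeasibleCalibrationError("target 0 requires shared_sd = 0")
        return 0.0
    floor, ceiling = simulated_rmse(0.0), simulated_rmse(cv_max)
    if floor > target_expert_rmse:
        if floor <= target_expert_rmse * (1.0 + rel_tol):
            return 0.0
        raise InfeasibleCalibrationError(
            f"target RMSE {target_expert_rmse} below the shared-error floor {floor:.3f}"
        )
    if ceiling < target_expert_rmse * (1.0 - rel_tol):
        raise InfeasibleCalibrationError(
            f"target RMSE {target_expert_rmse} unreachable with cv <= {cv_max} "
            f"(max {ceiling:.3f})"
        )
    lo, hi = 0.0, cv_max
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if simulated_rmse(mid) < target_expert_rmse:
            lo = mid
        else:
            hi = mid
    cv = 0.5 * (lo + hi)
    achieved = simulated_rmse(cv)
    if abs(achieved - target_expert_rmse) > rel_tol * target_expert_rmse:  # pragma: no cover
        raise InfeasibleCalibrationError(
            f"search stalled at RMSE {achieved:.3f} for target {target_expert_rmse}"
        )
    return cv


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_counts(n_participants: int, test_fraction: float = 0.20, train_tune_ratio: float = 4.0) -> tuple[int, int, int]:
    """(n_train, n_tune, n_test) under the documented rounding rule.

    The test count is the test fraction rounded to the nearest integer
    (half up); the remainder is split train:tune rounding the tune count to
    nearest (half up) with a floor of one tuning participant.
    """
    if n_participants < 10:
        raise SplitError(f"need at least 10 participants to split, got {n_participants}")
    n_test = _round_half_up(test_fraction * n_participants)
    remaining = n_participants - n_test
    n_tune = max(1, _round_half_up(remaining / (train_tune_ratio + 1.0)))
    n_train = remaining - n_tune
    if n_train < 1 or n_test < 1:
        raise SplitError("split produced an empty partition; increase cohort size")
    return n_train, n_tune, n_test


def split_cohort(
    cohort: pd.DataFrame,
    test_fraction: float = 0.20,
    train_tune_ratio: float = 4.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Assign train/tune/test labels by simple random sampling of participants.

    All scans of a participant share one label.  Returns a copy of the scan
    table with a ``split`` column.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    participants = np.unique(cohort["participant_id"].to_numpy())
    n_train, n_tune, n_test = split_counts(participants.size, test_fraction, train_tune_ratio)
    shuffled = rng.permutation(participants)
    label_of = {}
    for pid in shuffled[:n_test]:
        label_of[pid] = "test"
    for pid in shuffled[n_test:n_test + n_tune]:
        label_of[pid] = "tune"
    for pid in shuffled[n_test + n_tune:]:
        label_of[pid] = "train"
    out = cohort.copy()
    out["split"] = out["participant_id"].map(label_of)
    return out
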