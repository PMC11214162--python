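"""Simulated novice biometry and gross-error labelling.

Novice measurements are emulated by perturbing expert biometry with a
symmetric uniform RELATIVE error, independently per structure: a stated
average absolute error of ``a`` (e.g. 7.5%) corresponds to multipliers
``1 + u`` with ``u ~ Uniform(-2a, +2a)``, since the mean absolute value of
Uniform(-w, w) is w/2.  A "gross error" is a novice GA estimate differing
from the expert's by at least a stated number of days (base case 10, with
the boundary included).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from . import formulas
from .biometry import MEASUREMENTS, BiometrySet
from .errors import ConfigError, UnusableScanError
from .formulas import FormulaSpec

MAX_AVG_ABS_REL_ERROR = 0.25


def _check_level(avg_abs_rel_error: float) -> None:
    if not 0.0 <= avg_abs_rel_error <= MAX_AVG_ABS_REL_ERROR:
        raise ConfigError(
            f"average absolute relative error must lie in [0, {MAX_AVG_ABS_REL_ERROR}], "
            f"got {avg_abs_rel_error}"
        )


def draw_unit_perturbations(rng: np.random.Generator, shape) -> np.ndarray:
    """Uniform(-1, 1) draws to be scaled by 2a into relative errors.

    Kept separate from the scaling so a sensitivity grid can reuse one set
    of draws across error levels (common random numbers).
    """
    return rng.uniform(-1.0, 1.0, size=shape)


def multipliers_from_units(units: np.ndarray, avg_abs_rel_error: float) -> np.ndarray:
    """Turn unit draws into measurement multipliers 1 + Uniform(-2a, 2a)."""
    _check_level(avg_abs_rel_error)
    return 1.0 + 2.0 * avg_abs_rel_error * units


def perturb_biometry(
    biometry: BiometrySet,
    avg_abs_rel_error: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> BiometrySet:
    """Inject uniform random relative error into one scan's biometry.

    Each present measurement m becomes ``m * (1 + u)`` with
    ``u ~ Uniform(-2a, +2a)`` drawn independently per structure, so that
    ``E|u| = a``.  ``a = 0`` returns the input unchanged.
    """
    _check_level(avg_abs_rel_error)
    if avg_abs_rel_error == 0.0:
        return biometry
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = biometry.present()
    units = draw_unit_perturbations(rng, len(present))
    factors = multipliers_from_units(units, avg_abs_rel_error)
    return biometry.scaled(dict(zip(present, factors)))


def compute_novice_ga(
    novice_biometry: BiometrySet,
    spec: FormulaSpec,
    shared_dating_error: float = 0.0,
    *,
    range_slack: float = 0.0,
) -> float:
    """Novice GA: the dating formula on perturbed biometry, days.

    The novice shares the pregnancy's ground-truth reference, so the SAME
    shared dating error as the parent scan is added.  Measurement validity
    ranges are widened by ``range_slack`` (callers pass 2a) before a scan
    is declared unusable: a legitimate perturbation of an in-range value
    must never be rejected.
    """
    try:
        estimate = formulas.estimate_ga(novice_biometry, spec, range_slack=range_slack)
    except formulas.MeasurementRangeError as exc:
        raise UnusableScanError(str(exc)) from exc
    return estimate.ga_days + shared_dating_error


def label_gross_error(novice_ga: float, expert_ga: float, threshold_days: float) -> bool:
    """True iff the novice-expert GA discrepancy is at least the threshold.

    The boundary counts: a discrepancy of exactly ``threshold_days`` is a
    gross error.
    """
    if threshold_days <= 0:
        raise ConfigError("gross-error threshold must be positive")
    if not (np.isfinite(novice_ga) and np.isfinite(expert_ga)):
        raise ConfigError("GA estimates must be finite")
    return bool(abs(novice_ga - expert_ga) >= threshold_days)


def simulate_novice(
    cohort: pd.DataFrame,
    spec: FormulaSpec,
    avg_abs_rel_error: float,
    threshold_days: float = 10.0,
    *,
    seed: Union[int, np.random.Generator, None] = None,
    unit_perturbations: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Vectorised novice simulation over a scan table.

    Adds per-scan columns: ``novice_<m>`` for each measurement, the novice
    GA (``novice_ga``), the novice-expert discrepancy (``delta_vs_expert``),
    the gross-error label and a usability flag.  Scans whose perturbed
    measurements leave the 2a-widened validity envelope are flagged
    ``novice_usable = False`` (their novice GA is still recorded) and are
    meant to be excluded downstream; callers can count them from the flag.

    ``unit_perturbations`` (n_scans x 4 in [-1, 1]) overrides fresh draws,
    enabling common random numbers across error levels.
    """
    _check_level(avg_abs_rel_error)
    n = len(cohort)
    if unit_perturbations is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        unit_perturbations = draw_unit_perturbations(rng, (n, 4))
    units = np.asarray(unit_perturbations, dtype=float)
    if units.shape != (n, 4):
        raise ConfigError(f"unit_perturbations must have shape ({n}, 4)")

    factors = multipliers_from_units(units, avg_abs_rel_error)
    measured = {m: cohort[m].to_numpy() * factors[:, j] for j, m in enumerate(MEASUREMENTS)}

    slack = 2.0 * avg_abs_rel_error
    usable = np.ones(n, dtype=bool)
    for m in spec.required_inputs:
        lo, hi = spec.input_valid_ranges[m]
        usable &= (measured[m] >= lo * (1.0 - slack)) & (measured[m] <= hi * (1.0 + slack))

    novice_formula_ga = formulas._evaluate_terms(spec, measured)
    shared = cohort["shared_err"].to_numpy() if "shared_err" in cohort else 0.0
    novice_ga = novice_formula_ga + shared

    out = cohort.copy()
    for m in MEASUREMENTS:
        out[f"novice_{m}"] = measured[m]
    out["novice_ga"] = novice_ga
    out["delta_vs_expert"] = novice_ga - out["expert_ga"].to_numpy()
    out["gross_error"] = np.abs(out["delta_vs_expert"].to_numpy()) >= threshold_days
    out["novice_usable"] = usable
    return out
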