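"""Reference median fetal growth trajectory.

The cohort generator needs a "median fetus": a single monotone trajectory
giving typical BPD, HC, AC and FL as a function of one latent age, so that
biometry consistent with any chosen gestational age can be constructed by
sliding along it.  We use the international (Intergrowth-21st) fetal growth
standard median equations over 12-40 exact weeks, where all four medians
increase strictly, and extend each curve linearly beyond 40 weeks with its
terminal slope.  The extension matters because head growth in the published
standard flattens near term while the dating polynomials saturate, so latent
ages somewhat past 40 weeks are needed before the formulas return the top of
their gestational-age range.

The curves are tabulated at quarter-week resolution and interpolated with a
monotone (PCHIP) spline, so the trajectory is C1 and strictly increasing in
every measurement over the whole latent range.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .biometry import MEASUREMENTS

# Latent age range covered by the trajectory, in days.
LATENT_RANGE_DAYS = (84.0, 336.0)

_POLY_MAX_WEEKS = 40.0
_TABLE_MAX_WEEKS = 48.0
_STEP_WEEKS = 0.25


def _median_polynomials(t: np.ndarray) -> dict[str, np.ndarray]:
    """Published median equations, t in exact weeks, output in mm."""
    log_t = np.log(t)
    return {
        "bpd": 5.60878 + 0.158369 * t**2 - 0.00256379 * t**3,
        "hc": -28.2849 + 1.69267 * t**2 - 0.397485 * t**2 * log_t,
        "ac": -81.3243 + 11.6772 * t - 0.000561865 * t**3,
        "fl": -39.9616 + 4.32298 * t - 0.0380156 * t**2,
    }


def _build_table() -> tuple[np.ndarray, dict[str, np.ndarray]]:
    weeks = np.arange(12.0, _TABLE_MAX_WEEKS + _STEP_WEEKS / 2, _STEP_WEEKS)
    poly_part = weeks[weeks <= _POLY_MAX_WEEKS]
    medians = _median_polynomials(poly_part)
    # Terminal slope from the last tabulated step, per measurement.
    ext = weeks[weeks > _POLY_MAX_WEEKS]
    table: dict[str, np.ndarray] = {}
    for name in MEASUREMENTS:
        values = medians[name]
        slope = (values[-1] - values[-2]) / _STEP_WEEKS
        extension = values[-1] + slope * (ext - _POLY_MAX_WEEKS)
        table[name] = np.concatenate([values, extension])
    return weeks * 7.0, table


_LATENT_DAYS, _MEDIAN_TABLE = _build_table()
_SPLINES = {name: PchipInterpolator(_LATENT_DAYS, _MEDIAN_TABLE[name]) for name in MEASUREMENTS}


def reference_median(latent_age_days):
    """Median biometry (mm) at a latent age along the reference trajectory.

    Parameters
    ----------
    latent_age_days : float or ndarray
        Latent age in days, within ``LATENT_RANGE_DAYS``.

    Returns
    -------
    dict mapping measurement name -> value(s) in mm.
    """
    t = np.asarray(latent_age_days, dtype=float)
    lo, hi = LATENT_RANGE_DAYS
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError(f"latent age outside trajectory range [{lo}, {hi}] days")
    return {name: _SPLINES[name](t) for name in MEASUREMENTS}
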