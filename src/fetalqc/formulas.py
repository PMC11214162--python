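"""Gestational-age dating formulas driven by coefficient tables.

Published dating formulas estimate gestational age (GA) from fetal biometry
via low-order polynomials in the measurements (or their logarithms).  Two
are shipped as plain-text coefficient files:

* ``intergrowth21`` -- the Intergrowth-21st late-pregnancy formula,
  ln(GA days) = 3.813 + 0.03243 (ln HC)^2 + 0.001644 FL ln(HC), HC/FL in mm;
* ``hadlock`` -- the Hadlock four-parameter formula,
  GA weeks = 10.85 + 0.060 HC FL + 0.670 BPD + 0.168 AC, inputs in cm.

A formula is described entirely by its coefficient table: each coefficient
is keyed by a term string such as ``log(hc)^2`` or ``hc*fl`` (a product of
measurement factors, optionally log-transformed and/or raised to an integer
power; ``intercept`` is the constant term).  The ``transform`` field says
whether the polynomial gives GA directly (``linear_ga_polynomial``) or its
natural log (``log_ga_polynomial``).  Files declare their native measurement
unit (mm or cm) and native GA unit (days or weeks); the package converts so
that callers always pass millimetres and receive days.

``invert_formula`` produces the "median fetus" biometry for a target GA by
solving, along the reference median growth trajectory, for the single latent
age whose biometry the formula dates to that GA (bisection, tolerance
1e-3 days).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np

from . import growth
from .biometry import MEASUREMENTS, BiometrySet
from .errors import (
    FormulaLoadError,
    GARangeError,
    InversionError,
    MeasurementRangeError,
    MissingMeasurementError,
)

TRANSFORMS = ("log_ga_polynomial", "linear_ga_polynomial")
GA_DAYS_BOUNDS = (98.0, 300.0)
INVERSION_TOL_DAYS = 1e-3

_FACTOR_RE = re.compile(r"^(log\()?(bpd|hc|ac|fl)(\))?(?:\^(\d+))?$")


@dataclass(frozen=True)
class GAEstimate:
    """A gestational-age estimate in days, tagged with its provenance."""

    ga_days: float
    formula_name: str
    out_of_range: bool = False


@dataclass(frozen=True)
class FormulaSpec:
    """Validated description of a GA-from-biometry polynomial."""

    name: str
    transform: str
    measurement_unit: str  # native unit of the published coefficients
    ga_unit: str  # native GA unit of the published polynomial
    required_inputs: tuple[str, ...]
    coefficients: Mapping[str, float]
    ga_valid_range: tuple[float, float]  # days
    input_valid_ranges: Mapping[str, tuple[float, float]]  # mm

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise FormulaLoadError(f"unknown transform {self.transform!r}")
        if self.measurement_unit not in ("mm", "cm"):
            raise FormulaLoadError(f"unknown measurement unit {self.measurement_unit!r}")
        if self.ga_unit not in ("days", "weeks"):
            raise FormulaLoadError(f"unknown GA unit {self.ga_unit!r}")
        lo, hi = self.ga_valid_range
        if not (GA_DAYS_BOUNDS[0] <= lo < hi <= GA_DAYS_BOUNDS[1]):
            raise FormulaLoadError(
                f"ga_valid_range {self.ga_valid_range} must lie within {GA_DAYS_BOUNDS} days"
            )
        used = set()
        for term in self.coefficients:
            used.update(_parse_term(term))
        if used - set(MEASUREMENTS):
            raise FormulaLoadError(f"unknown measurements in terms: {sorted(used)}")
        if set(self.required_inputs) != used:
            raise FormulaLoadError(
                f"required_inputs {self.required_inputs} do not match the "
                f"measurements used by the terms {sorted(used)}"
            )
        for m in self.required_inputs:
            if m not in self.input_valid_ranges:
                raise FormulaLoadError(f"missing valid range for measurement {m!r}")
            lo_m, hi_m = self.input_valid_ranges[m]
            if not (0 < lo_m < hi_m):
                raise FormulaLoadError(f"invalid range for measurement {m!r}")


def _parse_term(term: str) -> tuple[str, ...]:
    """Measurements referenced by a coefficient term (empty for intercept)."""
    if term == "intercept":
        return ()
    names = []
    for factor in term.split("*"):
        match = _FACTOR_RE.match(factor)
        if match is None or bool(match.group(1)) != bool(match.group(3)):
            raise FormulaLoadError(f"cannot parse term factor {factor!r} in {term!r}")
        names.append(match.group(2))
    return tuple(names)


def _evaluate_terms(spec: FormulaSpec, values_mm: Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate the polynomial on measurement arrays (mm in, GA days out)."""
    unit_scale = 0.1 if spec.measurement_unit == "cm" else 1.0
    native = {m: np.asarray(values_mm[m], dtype=float) * unit_scale for m in spec.required_inputs}
    total = 0.0
    for term, coefficient in spec.coefficients.items():
        if term == "intercept":
            total = total + coefficient
            continue
        product = coefficient
        for factor in term.split("*"):
            match = _FACTOR_RE.match(factor)
            value = native[match.group(2)]
            if match.group(1):
                value = np.log(value)
            power = int(match.group(4)) if match.group(4) else 1
            product = product * value**power
        total = total + product
    ga = np.exp(total) if spec.transform == "log_ga_polynomial" else total
    if spec.ga_unit == "weeks":
        ga = ga * 7.0
    return np.asarray(ga, dtype=float)


def _check_ranges(spec: FormulaSpec, values: Mapping[str, float], slack: float) -> None:
    for m in spec.required_inputs:
        lo, hi = spec.input_valid_ranges[m]
        lo_s, hi_s = lo * (1.0 - slack), hi * (1.0 + slack)
        if not (lo_s <= values[m] <= hi_s):
            raise MeasurementRangeError(
                f"measurement {m!r} = {values[m]:.1f} mm outside valid range "
                f"[{lo_s:.1f}, {hi_s:.1f}] mm for formula {spec.name!r}"
            )


def estimate_ga(biometry: BiometrySet, spec: FormulaSpec, *, range_slack: float = 0.0) -> GAEstimate:
    """Estimate gestational age (days) from one scan's biometry.

    Parameters
    ----------
    biometry : BiometrySet
        Measurements in millimetres; every input the formula requires must
        be present.
    spec : FormulaSpec
        The dating formula to apply.
    range_slack : float
        Fractional widening of the published measurement validity ranges
        before rejecting an input.  Zero (strict) by default; simulation
        code passes a positive slack so that noisy perturbations of
        in-range values are never rejected.

    Returns
    -------
    GAEstimate
        GA in days.  Estimates outside the formula's valid GA range are
        returned flagged (``out_of_range=True``), never clamped: clamping
        would silently distort error distributions downstream.
    """
    values = biometry.as_dict()
    missing = [m for m in spec.required_inputs if m not in values]
    if missing:
        raise MissingMeasurementError(
            f"formula {spec.name!r} requires measurement(s) {missing} not present on this scan"
        )
    _check_ranges(spec, values, range_slack)
    ga = float(_evaluate_terms(spec, {m: values[m] for m in spec.required_inputs}))
    lo, hi = spec.ga_valid_range
    return GAEstimate(ga_days=ga, formula_name=spec.name, out_of_range=not lo <= ga <= hi)


def _ga_at_latent(spec: FormulaSpec, latent_days: np.ndarray) -> np.ndarray:
    medians = growth.reference_median(latent_days)
    return _evaluate_terms(spec, {m: medians[m] for m in spec.required_inputs})


def invert_formula_array(ga_days: np.ndarray, spec: FormulaSpec) -> dict[str, np.ndarray]:
    """Vectorised median-fetus inversion; returns measurement arrays in mm.

    Solves for the latent age on the reference trajectory at which the
    formula returns each requested GA, by bisection to 1e-3 days.  All
    four reference measurements are returned (not only the formula's
    inputs) so the generator can emit full biometry.
    """
    ga = np.atleast_1d(np.asarray(ga_days, dtype=float))
    lo_ga, hi_ga = spec.ga_valid_range
    if np.any(ga < lo_ga) or np.any(ga > hi_ga):
        raise GARangeError(
            f"target GA outside formula {spec.name!r} valid range [{lo_ga}, {hi_ga}] days"
        )
    lo = np.full_like(ga, growth.LATENT_RANGE_DAYS[0])
    hi = np.full_like(ga, growth.LATENT_RANGE_DAYS[1])
    f_lo = _ga_at_latent(spec, lo) - ga
    f_hi = _ga_at_latent(spec, hi) - ga
    if np.any(f_lo > 0) or np.any(f_hi < 0):
        raise InversionError(
            f"formula {spec.name!r} does not bracket GA range "
            f"[{ga.min():.1f}, {ga.max():.1f}] days over the reference trajectory "
            f"(ends: {f_lo.max() + ga.max():.1f}..{f_hi.min() + ga.min():.1f})"
        )
    # ~2^18 reduction of a 252-day bracket lands well below the tolerance.
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _ga_at_latent(spec, mid) < ga
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < INVERSION_TOL_DAYS:
            break
    else:  # pragma: no cover - 60 bisections always suffice
        raise InversionError("bisection failed to converge")
    latent = 0.5 * (lo + hi)
    return {m: np.asarray(v, dtype=float) for m, v in growth.reference_median(latent).items()}


def invert_formula(ga_days: float, spec: FormulaSpec) -> BiometrySet:
    """Median-fetus biometry whose formula GA equals ``ga_days``.

    Round-trip contract: ``estimate_ga(invert_formula(ga), spec).ga_days``
    agrees with ``ga`` to better than 0.1 days over the valid range.
    """
    arrays = invert_formula_array(np.asarray([float(ga_days)]), spec)
    return BiometrySet(**{m: float(v[0]) for m, v in arrays.items()})


# ---------------------------------------------------------------------------
# Coefficient-file I/O
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("name", "transform", "measurement_unit", "ga_unit", "required_inputs",
                  "ga_valid_range_days")


def _parse_coefficient_text(text: str, source: str) -> FormulaSpec:
    keys: dict[str, str] = {}
    coefficients: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormulaLoadError(f"{source}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = (part.strip() for part in line.partition("="))
        try:
            if key.startswith("coef "):
                coefficients[key[5:].strip()] = float(value)
            elif key.startswith("range "):
                lo, hi = (float(v) for v in value.split())
                ranges[key[6:].strip()] = (lo, hi)
            else:
                keys[key] = value
        except (ValueError, TypeError) as exc:
            raise FormulaLoadError(f"{source}:{lineno}: cannot parse {line!r}: {exc}") from exc
    missing = [k for k in _REQUIRED_KEYS if k not in keys]
    if missing:
        raise FormulaLoadError(f"{source}: missing required field(s) {missing}")
    if not coefficients:
        raise FormulaLoadError(f"{source}: no coefficients found")
    try:
        ga_lo, ga_hi = (float(v) for v in keys["ga_valid_range_days"].split())
    except ValueError as exc:
        raise FormulaLoadError(f"{source}: bad ga_valid_range_days: {exc}") from exc
    unit_scale = 10.0 if keys["measurement_unit"] == "cm" else 1.0  # ranges -> mm
    spec = FormulaSpec(
        name=keys["name"],
        transform=keys["transform"],
        measurement_unit=keys["measurement_unit"],
        ga_unit=keys["ga_unit"],
        required_inputs=tuple(keys["required_inputs"].split()),
        coefficients=coefficients,
        ga_valid_range=(ga_lo, ga_hi),
        input_valid_ranges={m: (lo * unit_scale, hi * unit_scale) for m, (lo, hi) in ranges.items()},
    )
    _check_monotone(spec, source)
    return spec


def _check_monotone(spec: FormulaSpec, source: str, n_grid: int = 41) -> None:
    """Numeric sweep: GA must strictly increase in each required input."""
    mid = {m: 0.5 * (lo + hi) for m, (lo, hi) in spec.input_valid_ranges.items()}
    for m in spec.required_inputs:
        lo, hi = spec.input_valid_ranges[m]
        sweep = np.linspace(lo, hi, n_grid)
        values = {k: np.full(n_grid, v) for k, v in mid.items()}
        values[m] = sweep
        ga = _evaluate_terms(spec, values)
        if not np.all(np.diff(ga) > 0):
            raise FormulaLoadError(
                f"{source}: formula {spec.name!r} is not strictly increasing in {m!r}"
            )


def load_formula(coefficient_file: Union[str, Path]) -> FormulaSpec:
    """Load and validate a formula from a flat key-value coefficient file."""
    path = Path(coefficient_file)
    if not path.exists():
        raise FormulaLoadError(f"coefficient file not found: {path}")
    return _parse_coefficient_text(path.read_text(), str(path))


def write_spec(spec: FormulaSpec, coefficient_file: Union[str, Path]) -> None:
    """Serialize a FormulaSpec back to the flat key-value format."""
    unit_scale = 0.1 if spec.measurement_unit == "cm" else 1.0  # mm -> native
    lines = [
        f"name = {spec.name}",
        f"transform = {spec.transform}",
        f"measurement_unit = {spec.measurement_unit}",
        f"ga_unit = {spec.ga_unit}",
        f"required_inputs = {' '.join(spec.required_inputs)}",
        f"ga_valid_range_days = {spec.ga_valid_range[0]:g} {spec.ga_valid_range[1]:g}",
    ]
    lines += [f"coef {term} = {value!r}" for term, value in spec.coefficients.items()]
    lines += [
        f"range {m} = {lo * unit_scale:g} {hi * unit_scale:g}"
        for m, (lo, hi) in spec.input_valid_ranges.items()
    ]
    Path(coefficient_file).write_text("\n".join(lines) + "\n")


def get_formula(name: str) -> FormulaSpec:
    """Load one of the formulas shipped with the package by short name."""
    package_files = resources.files("fetalqc.data")
    candidate = package_files / f"{name}.txt"
    if not candidate.is_file():
        shipped = sorted(p.name[:-4] for p in package_files.iterdir() if p.name.endswith(".txt"))
        raise FormulaLoadError(f"no shipped formula {name!r}; available: {shipped}")
    return _parse_coefficient_text(candidate.read_text(), f"fetalqc.data/{name}.txt")
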