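"""End-to-end experiment orchestration.

``run_base_case`` executes the full pipeline once: generate a cohort,
split it at the participant level, simulate novice biometry at the base
error level, calibrate guardrail cut-points on the tuning split at the
target sensitivities, and evaluate them on the test split -- alongside the
model-vs-expert accuracy comparison.  ``run_sensitivity_grid`` repeats the
guardrail AUC over a grid of novice error levels and gross-error
definitions, optionally with an inflated model-error scale emulating a
degraded (e.g. truncated-input) model; all grid cells share the same
cohort and the same unit perturbation draws (common random numbers), so
the grid's monotone structure is visible without enormous cohorts.

Everything is reproducible from one master seed: a seed sequence is spawned
into one child per stage (cohort, split, novice, subsample), so changing a
downstream stage never disturbs an upstream one.
"""

from __future__ import annotations

import dataclasses
import json
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, formulas, guardrail, novice, stats
from .cohort import (
    CohortConfig,
    ErrorModel,
    GADistribution,
    ScaleMixture,
    generate_cohort,
    split_cohort,
)
from .errors import ConfigError, FetalQCError
from .guardrail import GuardrailResult
from .stats import ComparisonReport

_STAGE_RNG_NAMES = ("cohort", "split", "novice", "subsample")


@contextmanager
def _stage(name: str):
    """Attach the pipeline stage name to any package error raised inside."""
    try:
        yield
    except FetalQCError as exc:
        exc.stage = name
        raise


def stage_generators(master_seed: int) -> dict[str, np.random.Generator]:
    """One independent generator per pipeline stage, spawned from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGE_RNG_NAMES))
    return {name: np.random.default_rng(seq) for name, seq in zip(_STAGE_RNG_NAMES, children)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the full analysis (base case + sensitivity grids)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    novice_error_levels: tuple[float, ...] = (0.05, 0.075, 0.10)
    gross_error_definitions: tuple[float, ...] = (7.0, 10.0, 14.0)
    target_sensitivities: tuple[float, ...] = (0.80, 0.90, 0.95)
    base_novice_error: float = 0.075
    base_definition_days: float = 10.0
    model_degradation_factor: float = 1.0
    flag_reference: str = "novice"  # statistic is |model - novice| or |model - expert|
    min_tuning_positives: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_novice_error not in self.novice_error_levels:
            raise ConfigError("base novice error level must appear in the grid")
        if self.base_definition_days not in self.gross_error_definitions:
            raise ConfigError("base gross-error definition must appear in the grid")
        if self.model_degradation_factor < 1.0:
            raise ConfigError("model_degradation_factor must be >= 1")
        if self.flag_reference not in ("novice", "expert"):
            raise ConfigError("flag_reference must be 'novice' or 'expert'")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        return json.loads(json.dumps(raw))  # plain lists/floats only

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        cohort_data = dict(data.pop("cohort", {}))
        if "ga_distribution" in cohort_data:
            ga = dict(cohort_data["ga_distribution"])
            cohort_data["ga_distribution"] = GADistribution(
                p_second=ga["p_second"],
                second=tuple(ga["second"]),
                third=tuple(ga["third"]),
            )
        if "error_model" in cohort_data:
            em = dict(cohort_data["error_model"])
            mixture = em.get("model_mixture")
            if mixture is not None:
                em["model_mixture"] = ScaleMixture(
                    weights=tuple(mixture["weights"]), sds=tuple(mixture["sds"])
                )
            cohort_data["error_model"] = ErrorModel(**em)
        for key in ("novice_error_levels", "gross_error_definitions", "target_sensitivities"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(cohort=CohortConfig(**cohort_data), **data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class SensitivityGrid:
    """AUC over (gross-error definition) x (novice error level) cells."""

    degradation_factor: float
    auc: pd.DataFrame  # index: definitions (days); columns: error levels
    missing: dict[tuple[float, float], str]  # (definition, level) -> reason

    def to_dict(self) -> dict:
        return {
            "degradation_factor": self.degradation_factor,
            "definitions_days": [float(v) for v in self.auc.index],
            "novice_error_levels": [float(v) for v in self.auc.columns],
            "auc": [[None if np.isnan(v) else float(v) for v in row] for row in self.auc.to_numpy()],
            "missing": {f"{d}|{a}": reason for (d, a), reason in self.missing.items()},
        }


@dataclass(frozen=True)
class BaseCaseResult:
    config: ExperimentConfig
    split_participant_counts: dict[str, int]
    n_unusable: int
    comparison: ComparisonReport
    comparison_single_scan: ComparisonReport
    thresholds: dict[float, float]  # target sensitivity -> days
    tuning_sensitivity: dict[float, float]
    guardrail: dict[float, GuardrailResult]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "split_participant_counts": self.split_participant_counts,
            "n_unusable": self.n_unusable,
            "comparison": self.comparison.to_dict(),
            "comparison_single_scan": self.comparison_single_scan.to_dict(),
            "thresholds_days": {str(k): v for k, v in self.thresholds.items()},
            "tuning_sensitivity": {str(k): v for k, v in self.tuning_sensitivity.items()},
            "guardrail": {str(k): v.to_dict() for k, v in self.guardrail.items()},
        }


def simulate_scans(config: ExperimentConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate, split, and novice-perturb one cohort; returns (scans, unit draws)."""
    rngs = stage_generators(config.master_seed)
    spec = formulas.get_formula(config.cohort.formula_name)
    with _stage("generate"):
        scans = generate_cohort(config.cohort, rng=rngs["cohort"])
    with _stage("split"):
        scans = split_cohort(
            scans, config.cohort.test_fraction, config.cohort.train_tune_ratio, rng=rngs["split"]
        )
    units = novice.draw_unit_perturbations(rngs["novice"], (len(scans), 4))
    with _stage("novice"):
        scans = novice.simulate_novice(
            scans, spec, config.base_novice_error, config.base_definition_days,
            unit_perturbations=units,
        )
    return scans, units


def _flag_statistic(scans: pd.DataFrame, config: ExperimentConfig, model_ga=None) -> np.ndarray:
    model = scans["model_ga"].to_numpy() if model_ga is None else model_ga
    reference = "novice_ga" if config.flag_reference == "novice" else "expert_ga"
    return guardrail.compute_flag_statistic(model, scans[reference].to_numpy())


def run_base_case(config: ExperimentConfig) -> BaseCaseResult:
    """Execute the full base-case analysis, reproducibly from the master seed."""
    scans, _ = simulate_scans(config)
    rngs = stage_generators(config.master_seed)
    usable = scans[scans["novice_usable"]]
    tune = usable[usable["split"] == "tune"]
    test = usable[usable["split"] == "test"]

    with _stage("comparison"):
        table = stats.paired_error_table(scans[scans["split"] == "test"])
        comparison = stats.comparison_report(table)
        single = stats.one_scan_per_participant(table, rng=rngs["subsample"])
        comparison_single = stats.comparison_report(single)

    with _stage("calibrate"):
        thresholds = guardrail.calibrate_thresholds(
            _flag_statistic(tune, config),
            tune["gross_error"].to_numpy(),
            config.target_sensitivities,
            min_positives=config.min_tuning_positives,
        )
        tune_stats = _flag_statistic(tune, config)
        tune_labels = tune["gross_error"].to_numpy()
        tuning_sensitivity = {
            target: float(np.mean(tune_stats[tune_labels] >= t))
            for target, t in thresholds.items()
        }

    with _stage("evaluate"):
        test_stats = _flag_statistic(test, config)
        test_labels = test["gross_error"].to_numpy()
        results = {
            target: guardrail.evaluate_guardrail(test_stats, test_labels, t)
            for target, t in thresholds.items()
        }

    counts = scans.groupby("split")["participant_id"].nunique().to_dict()
    return BaseCaseResult(
        config=config,
        split_participant_counts={k: int(v) for k, v in counts.items()},
        n_unusable=int((~scans["novice_usable"]).sum()),
        comparison=comparison,
        comparison_single_scan=comparison_single,
        thresholds=thresholds,
        tuning_sensitivity=tuning_sensitivity,
        guardrail=results,
    )


def run_sensitivity_grid(config: ExperimentConfig) -> dict[float, SensitivityGrid]:
    """Guardrail AUC grids over (definition, error level), per degradation factor.

    Factor 1.0 is the full-quality model; a factor above 1 multiplies the
    model's independent error component, emulating degraded model inputs.
    All cells share one cohort and one set of unit perturbation draws.
    """
    scans, units = simulate_scans(config)
    spec = formulas.get_formula(config.cohort.formula_name)
    factors = [1.0]
    if config.model_degradation_factor > 1.0:
        factors.append(config.model_degradation_factor)

    base_model = scans["true_ga"].to_numpy() + scans["shared_err"].to_numpy()
    indep = scans["model_indep_err"].to_numpy()

    grids: dict[float, SensitivityGrid] = {}
    for factor in factors:
        model_ga = base_model + factor * indep
        auc = pd.DataFrame(
            index=pd.Index(config.gross_error_definitions, name="definition_days"),
            columns=pd.Index(config.novice_error_levels, name="novice_error"),
            dtype=float,
        )
        missing: dict[tuple[float, float], str] = {}
        for level in config.novice_error_levels:
            with _stage("novice"):
                perturbed = novice.simulate_novice(
                    scans, spec, level, config.base_definition_days, unit_perturbations=units
                )
            mask = (perturbed["split"] == "test").to_numpy() & perturbed["novice_usable"].to_numpy()
            delta = np.abs(perturbed["delta_vs_expert"].to_numpy()[mask])
            cell_stats = _flag_statistic(perturbed.loc[mask], config, model_ga=model_ga[mask])
            for definition in config.gross_error_definitions:
                labels = delta >= definition
                if labels.all() or not labels.any():
                    missing[(definition, level)] = (
                        "all test scans on one side of the gross-error definition"
                    )
                    auc.loc[definition, level] = np.nan
                    continue
                value, _, _ = guardrail.delong_auc_ci(cell_stats, labels)
                auc.loc[definition, level] = value
        grids[factor] = SensitivityGrid(degradation_factor=factor, auc=auc, missing=missing)
    return grids


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _comparison_frame(report: ComparisonReport) -> pd.DataFrame:
    rows = [
        ("MAE (days)", report.mae_model, report.mae_expert, report.mae_comparison),
        ("RMSE (days)", report.rmse_model, report.rmse_expert, report.rmse_comparison),
    ]
    for name, block in report.trimesters.items():
        rows.append(
            (f"{name} trimester MAE (days)", block["mae_model"], block["mae_expert"],
             block["mae_comparison"])
        )
    records = [
        {
            "quantity": label,
            "model": round(m[0], 2),
            "model_se": round(m[1], 2),
            "expert": round(e[0], 2),
            "expert_se": round(e[1], 2),
            "difference": round(c.difference, 2),
            "ci_lower": round(c.ci[0], 2),
            "ci_upper": round(c.ci[1], 2),
        }
        for label, m, e, c in rows
    ]
    w = report.within_cutoff
    records.append(
        {
            "quantity": f"Absolute error < {w.cutoff_days:g} days (%)",
            "model": round(100 * w.p_model, 1),
            "model_se": round(100 * w.se_model, 1),
            "expert": round(100 * w.p_expert, 1),
            "expert_se": round(100 * w.se_expert, 1),
            "difference": round(100 * w.difference, 1),
            "ci_lower": round(100 * w.wald_ci[0], 1),
            "ci_upper": round(100 * w.wald_ci[1], 1),
        }
    )
    return pd.DataFrame.from_records(records)


def _guardrail_frame(base: BaseCaseResult) -> pd.DataFrame:
    records = []
    for target, result in base.guardrail.items():
        row = {
            "tuning_target_sensitivity_pct": round(100 * target, 0),
            "threshold_days": round(result.threshold_days, 1),
        }
        for name, triple in (
            ("sensitivity", result.sensitivity),
            ("specificity", result.specificity),
            ("ppv", result.ppv),
            ("npv", result.npv),
        ):
            row[f"{name}_pct"] = round(100 * triple[0], 1)
            row[f"{name}_ci"] = f"({100 * triple[1]:.1f}, {100 * triple[2]:.1f})"
        row["auc"] = round(result.auc[0], 2)
        row["auc_ci"] = f"({result.auc[1]:.2f}, {result.auc[2]:.2f})"
        records.append(row)
    return pd.DataFrame.from_records(records)


def _grid_frame(grids: dict[float, SensitivityGrid]) -> pd.DataFrame:
    frames = []
    for factor, grid in grids.items():
        rendered = grid.auc.round(2).astype(object)
        for (definition, level), reason in grid.missing.items():
            rendered.loc[definition, level] = f"NA({reason})"
        rendered = rendered.reset_index()
        rendered.insert(0, "degradation_factor", factor)
        frames.append(rendered)
    return pd.concat(frames, ignore_index=True)


def render_reports(base: BaseCaseResult, grids: Optional[dict[float, SensitivityGrid]], out_dir) -> list[Path]:
    """Write CSV/JSON report tables plus a run manifest; idempotent.

    The manifest carries the full configuration, master seed and package
    version: re-running the pipeline from a manifest reproduces the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_json(name: str, payload) -> None:
        path = out / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)

    def _write_csv(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    _write_csv("comparison.csv", _comparison_frame(base.comparison))
    _write_json("comparison.json", base.comparison.to_dict())
    _write_csv("comparison_single_scan.csv", _comparison_frame(base.comparison_single_scan))
    _write_csv("guardrail.csv", _guardrail_frame(base))
    _write_json("guardrail.json", {str(k): v.to_dict() for k, v in base.guardrail.items()})
    _write_json("thresholds.json", {str(k): v for k, v in base.thresholds.items()})
    if grids:
        _write_csv("sensitivity_grid.csv", _grid_frame(grids))
        _write_json("sensitivity_grid.json", {str(f): g.to_dict() for f, g in grids.items()})
    _write_json(
        "manifest.json",
        {
            "package": "fetalqc",
            "version": __version__,
            "master_seed": base.config.master_seed,
            "config": base.config.to_dict(),
        },
    )
    return written
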