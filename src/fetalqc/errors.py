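"""Exception hierarchy.

Every failure mode the pipeline can hit deliberately has its own class so
that orchestration code can re-raise with stage context without string
matching.
"""


class FetalQCError(Exception):
    """Base class for all package errors."""


class FormulaError(FetalQCError):
    """Base class for dating-formula errors."""


class FormulaLoadError(FormulaError):
    """Coefficient file is malformed, incomplete, or fails validation."""


class MissingMeasurementError(FormulaError):
    """A measurement required by the formula is absent."""


class MeasurementRangeError(FormulaError):
    """A measurement lies outside the formula's validity range."""


class GARangeError(FormulaError):
    """Requested gestational age is outside the formula's valid range."""


class InversionError(FormulaError):
    """Root-finding for the median-fetus inversion failed to converge."""


class ConfigError(FetalQCError):
    """Invalid configuration value."""


class InfeasibleCalibrationError(FetalQCError):
    """A moment pair or error target cannot be met by the model family."""


class SplitError(FetalQCError):
    """Cohort too small (or otherwise unfit) to split."""


class UnusableScanError(FetalQCError):
    """Perturbed biometry left the widened validity envelope."""


class CalibrationError(FetalQCError):
    """Threshold calibration impossible (e.g. no gross-error positives)."""


class DegenerateEvaluationError(FetalQCError):
    """Test-set evaluation requested with a single outcome class."""


class DegenerateTestError(FetalQCError):
    """A statistical test's sampling distribution is degenerate."""


class StageError(FetalQCError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
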