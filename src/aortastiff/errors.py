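"""Exception hierarchy for the aortastiff package."""


class AortaStiffError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(AortaStiffError, ValueError):
    """An argument violates a documented precondition."""


class NoSignalError(AortaStiffError):
    """A flow curve carries no usable pulse (flat, or no detectable upslope)."""


class LowQualityError(AortaStiffError):
    """A delay estimate failed its quality gate (e.g. empty admissible
    time-frequency region, correlation peak below threshold)."""


class InsufficientDataError(AortaStiffError):
    """Too few valid observations remain to produce an estimate."""


class NonPhysiologicalFitError(AortaStiffError):
    """A fitted pulse wave velocity is zero, negative or non-finite."""


class CalibrationError(AortaStiffError):
    """A copula calibration target is unreachable; carries the attainable range."""

    def __init__(self, message: str, attainable: tuple[float, float] | None = None):
        super().__init__(message)
        self.attainable = attainable


class SchemaError(AortaStiffError, ValueError):
    """A tabular file does not match its documented schema."""


class ConfigError(AortaStiffError, ValueError):
    """A run configuration is missing keys or contains unknown ones."""
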