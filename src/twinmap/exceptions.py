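"""Exception hierarchy shared across the pipeline stages."""


class TwinmapError(Exception):
    """Base class for all package errors."""


class SchemaError(TwinmapError):
    """A mandatory column is missing or mis-declared in the input table."""


class EmptyInputError(TwinmapError):
    """An operation that requires data received none."""


class DomainError(TwinmapError, ValueError):
    """A value lies outside its clinically valid domain."""


class IncompleteRecordError(TwinmapError):
    """A record with missing predictor fields reached a complete-case stage."""


class ConfigError(TwinmapError, ValueError):
    """Invalid generator or run configuration."""


class SplitError(TwinmapError):
    """Reference/model split cannot be performed."""


class CalibrationError(TwinmapError):
    """Reference group too small (or otherwise unusable) for calibration."""


class NotFittedError(TwinmapError, RuntimeError):
    """A model was used before being fitted."""


class EmbeddingError(TwinmapError):
    """Too few rows (or degenerate input) for manifold embedding."""


class InsufficientArmError(TwinmapError):
    """A treatment arm has fewer patients than the requested neighbor count."""

    def __init__(self, arm: str, available: int, requested: int):
        self.arm = arm
        self.available = available
        self.requested = requested
        super().__init__(
            f"treatment arm '{arm}' has only {available} patients, "
            f"need at least {requested}"
        )


class DegenerateSampleError(TwinmapError):
    """A point sample is too small or degenerate for density estimation."""


class EvaluationError(TwinmapError):
    """Predictor evaluation cannot run (e.g. a single outcome class)."""
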