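"""Exception hierarchy for the pipeline.

All domain-specific errors derive from :class:`SedpepError` so callers can
catch pipeline failures without masking programming errors.
"""


class SedpepError(Exception):
    """Base class for all pipeline errors."""


class InvalidDesignError(SedpepError, ValueError):
    """An assay or observation design is insufficient (e.g. too few
    substrate concentrations to constrain a saturation curve)."""


class DomainError(SedpepError, ValueError):
    """An input value lies outside its physical domain (negative
    concentration, nonpositive sedimentation rate, ...)."""


class ConfigurationError(SedpepError, ValueError):
    """A required configuration item is missing or inconsistent."""


class DataQualityError(SedpepError, ValueError):
    """Inputs are formally valid but produce a physically impossible
    result (e.g. porosity outside (0, 1))."""


class ValidationError(SedpepError, ValueError):
    """A table fails schema-level validation (duplicate ids, unknown
    category labels)."""


class SolverError(SedpepError, RuntimeError):
    """The reaction-transport solver failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CalibrationError(SedpepError, RuntimeError):
    """All calibration starts failed."""
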