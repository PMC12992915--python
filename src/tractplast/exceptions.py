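"""Exception hierarchy for tractplast."""


class TractplastError(Exception):
    """Base class for all package errors."""


class SchemaError(TractplastError):
    """Input table is missing required columns or has malformed values."""


class IntegrityError(TractplastError):
    """Input table violates a uniqueness/completeness invariant."""


class ConfigurationError(TractplastError):
    """A configuration object is internally inconsistent."""


class CalibrationError(TractplastError):
    """g-ratio calibration has no valid solution."""


class ConvergenceError(TractplastError):
    """An iterative fit failed to converge."""
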