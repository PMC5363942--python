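"""Exception hierarchy for racvd."""


class RacvdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RacvdError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(RacvdError):
    """Cohort data violates the column schema or a record invariant."""


class UnitError(RacvdError):
    """Unsupported unit conversion."""


class EquationError(RacvdError):
    """Risk-equation file invalid, corrupted, or evaluated on unsuitable input."""


class FitError(RacvdError):
    """Model estimation failed (separation, empty stratum, degenerate input)."""
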