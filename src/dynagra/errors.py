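"""Exception hierarchy for dynagra.

All package-specific failures derive from :class:`DynagraError` so callers
(and the CLI) can distinguish data/validation problems from genuine bugs.
"""


class DynagraError(Exception):
    """Base class for all dynagra errors."""


class PanelIntegrityError(DynagraError):
    """Duplicate cells or violated panel invariants in monitoring data."""


class TimestampParseError(DynagraError):
    """A timestamp could not be parsed; the message names the offending row."""


class FrequencyError(DynagraError):
    """Native sampling cannot be snapped onto a uniform hourly grid."""


class DataError(DynagraError):
    """Missing values or otherwise unusable data inside a computation."""


class LengthError(DynagraError):
    """A sequence is too short for the requested operation."""


class DomainError(DynagraError):
    """An input lies outside the mathematical domain of an operation."""


class ShapeError(DynagraError):
    """Mismatched sequence lengths or array shapes."""


class LookupError_(DynagraError):
    """Unknown station or variable requested from a panel."""


class DegeneracyError(DynagraError):
    """Singular correlation matrix (collinear or constant series)."""


class ConfigError(DynagraError):
    """Invalid configuration values."""


class ValidationError(DynagraError):
    """Invalid synthetic-scenario specification."""


class NotComputableError(DynagraError):
    """The requested time point has insufficient history."""
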