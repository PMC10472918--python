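"""Exception hierarchy shared across the package.

All configuration / input problems raise subclasses of :class:`SpatenError`
so callers can catch one base class at pipeline level.
"""


class SpatenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SpatenError, ValueError):
    """A configuration object or argument is invalid."""


class InvalidInputError(SpatenError, ValueError):
    """Data passed to an operation violates its preconditions."""


class InsufficientDataError(SpatenError, RuntimeError):
    """A recording cannot supply the requested number of segments."""


class DegenerateInputError(SpatenError, ValueError):
    """Input is numerically degenerate (e.g. zero variance)."""


class ConvergenceError(SpatenError, RuntimeError):
    """An iterative estimator (ICA) failed to converge."""


class SchemaError(SpatenError, ValueError):
    """A file does not contain the expected channels / columns."""


class RejectedRecordingError(SpatenError, RuntimeError):
    """A recording is rejected by dataset policy (e.g. sampling rate != 250 Hz)."""


class UndefinedMetricError(SpatenError, ValueError):
    """A metric is undefined for the given counts (e.g. an empty class)."""


class DegenerateStatisticError(SpatenError, ValueError):
    """A test statistic is undefined (e.g. zero variance of differences)."""
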