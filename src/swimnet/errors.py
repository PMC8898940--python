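"""Exception hierarchy.

Everything raised on bad scientific input derives from :class:`SwimnetError`
so callers can catch one base class; most are also ``ValueError`` subclasses
so they behave sensibly in generic numeric code.
"""


class SwimnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(SwimnetError, ValueError):
    """A timing or distance that cannot come from a real trial (e.g. t <= 0)."""


class InvalidAnthropometricsError(SwimnetError, ValueError):
    """Anthropometric inputs that are non-positive or internally inconsistent
    (sitting height >= stature)."""


class UndefinedChangeError(SwimnetError, ValueError):
    """Percent change requested with a zero baseline."""


class PairingError(SwimnetError, ValueError):
    """Before/after sessions that cannot be paired (id mismatch, missing trial,
    unpaired swimmer)."""


class InsufficientSampleError(SwimnetError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(SwimnetError, ValueError):
    """Zero-variance or otherwise degenerate data (constant vector, identical
    before/after differences, zero-variance column, both SDs zero)."""


class ConvergenceError(SwimnetError, RuntimeError):
    """Iterative solver failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SchemaError(SwimnetError, ValueError):
    """Input table does not conform to the expected column schema; names the
    offending columns."""


class ConstructionError(SwimnetError, RuntimeError):
    """Random-structure construction failed after the retry budget."""


class ConfigError(SwimnetError, ValueError):
    """Invalid simulation or run configuration."""
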