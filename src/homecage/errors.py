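"""Exception hierarchy for the homecage toolkit."""


class HomecageError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(HomecageError):
    """A file does not match the documented column schema."""


class OrderingError(HomecageError):
    """Timestamps in a log are not non-decreasing."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(HomecageError):
    """A record violates a data-model invariant."""


class UnknownTagError(HomecageError):
    """An RFID tag does not resolve to a roster entry."""


class ProtocolError(HomecageError):
    """Inconsistent or out-of-range protocol configuration."""


class ConfigError(HomecageError):
    """Invalid simulator or run configuration."""


class InsufficientDataError(HomecageError):
    """Not enough observations for the requested estimate."""


class FitError(HomecageError):
    """Nonlinear fit failed to converge; carries diagnostics."""


class MetricError(HomecageError):
    """A metric's preconditions are not met by the supplied ledger."""
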