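"""Exception hierarchy shared across the package."""


class StressclockError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StressclockError, ValueError):
    """Raised when input data violate a documented invariant."""


class ParseError(StressclockError, ValueError):
    """Raised when a file cannot be parsed; names the offending line."""


class ConfigurationError(StressclockError, ValueError):
    """Raised for invalid or inconsistent configuration values."""


class DegenerateInputError(StressclockError, ValueError):
    """Raised when a statistic is undefined for the given data (e.g. zero variance)."""
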