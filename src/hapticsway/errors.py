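"""Exception hierarchy used across the package."""


class HapticSwayError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HapticSwayError, ValueError):
    """Invalid or inconsistent parameter / configuration values."""


class InvalidNumericError(HapticSwayError, ValueError):
    """Non-finite state, input or parameter where finite values are required."""


class SchemaError(HapticSwayError, ValueError):
    """Trial file does not conform to the expected schema."""


class IntegrityError(HapticSwayError, ValueError):
    """File contents contradict their own declared metadata."""


class UndefinedCorrelationError(HapticSwayError, ValueError):
    """Correlation requested for a zero-variance signal."""


class FitError(HapticSwayError, RuntimeError):
    """All optimisation starts failed to converge."""
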