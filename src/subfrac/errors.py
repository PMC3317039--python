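"""Exception hierarchy shared across the package."""


class SubfracError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SubfracError, ValueError):
    """Raised when an input value violates a documented precondition."""


class ConfigurationError(SubfracError, KeyError):
    """Raised when a configuration (channel map, run config) is incomplete."""


class TraceFailureError(SubfracError, RuntimeError):
    """Raised when automated membrane tracing finds no usable contour.

    Callers holding a manually traced contour should fall back to it.
    """
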