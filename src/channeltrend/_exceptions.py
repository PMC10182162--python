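"""Exception types shared across the package."""


class ChannelTrendError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ChannelTrendError, ValueError):
    """A parameter is outside its valid domain."""


class InvalidInputError(ChannelTrendError, ValueError):
    """Input data violate a precondition (shape, range, dtype)."""


class IntegrationFailureError(ChannelTrendError, RuntimeError):
    """The fixed-step integrator produced a divergent voltage trace."""


class PerfectSeparationError(ChannelTrendError, RuntimeError):
    """The logistic MLE is unbounded (data are linearly separable)."""


class FormatError(ChannelTrendError, ValueError):
    """A data file does not follow the expected on-disk format."""
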