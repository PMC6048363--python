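"""Exception hierarchy.

Every error raised by the package derives from :class:`SaspkitError` so
callers can catch pipeline failures with a single handler while still
discriminating between malformed inputs, degenerate statistics and
misconfigured parameters.
"""


class SaspkitError(Exception):
    """Base class for all package errors."""


class FormatError(SaspkitError):
    """A file or table violates its documented format."""


class ConfigError(SaspkitError):
    """Unknown or invalid configuration key/value."""


class ParameterError(SaspkitError):
    """An argument is outside its documented domain."""


class CapacityError(ParameterError):
    """A simulated layout cannot accommodate the requested design."""


class CoverageError(SaspkitError):
    """Required observations are missing (readouts, replicates, events)."""


class DegenerateInputError(SaspkitError):
    """Input is valid but statistically degenerate (zero MAD, equal controls...)."""


class SampleSizeError(SaspkitError):
    """Too few observations for the requested statistic."""


class BimodalityError(SaspkitError):
    """A distribution required to be bimodal is not."""
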