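"""Exception hierarchy for clonescope.

Every error raised by the package derives from :class:`ClonescopeError`, so
callers (and the CLI) can catch pipeline failures without masking genuine
programming errors.
"""


class ClonescopeError(Exception):
    """Base class for all clonescope errors."""


class ConfigurationError(ClonescopeError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(ClonescopeError):
    """Malformed input data (negative counts, duplicate keys, bad types)."""


class ReferentialIntegrityError(ValidationError):
    """A table references cell or site ids absent from the metadata tables."""


class SchemaError(ValidationError):
    """A delimited file does not match its declared schema."""


class ConsistencyError(ClonescopeError):
    """An internal invariant was violated (e.g. an unclassified signature site)."""


class UndefinedStatisticError(ClonescopeError):
    """A statistic is undefined for the given input (e.g. no qualified cells).

    Raised instead of silently returning 0, so a donor with no usable data is
    never conflated with a donor measured at zero.
    """


class EmptyStratumError(ClonescopeError):
    """A stratified comparison has a stratum with no donors."""
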