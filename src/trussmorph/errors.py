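"""Exception hierarchy shared across the pipeline."""


class TrussMorphError(Exception):
    """Base class for all package errors."""


class ParseError(TrussMorphError):
    """A file could not be parsed; the message names the record or line."""


class ValidationError(TrussMorphError):
    """Input data violates an invariant (counts, signs, missing labels)."""


class ConfigurationError(TrussMorphError):
    """A requested option or column does not match the supplied data."""


class DomainError(TrussMorphError):
    """An argument is outside the mathematical domain of an operation."""


class SingularityError(TrussMorphError):
    """A pooled covariance (or similar matrix) is not invertible."""
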