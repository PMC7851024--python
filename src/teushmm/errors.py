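"""Exception hierarchy for teushmm."""


class TeushmmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TeushmmError, ValueError):
    """An input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A file could not be parsed into the expected structure."""


class SchemaError(ParseError):
    """A serialized artifact declares an unsupported schema version."""


class IntegrityError(ValidationError):
    """A loaded artifact violates a model invariant (e.g. non-stochastic rows)."""


class NumericalError(TeushmmError, RuntimeError):
    """A computation produced non-finite values."""
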