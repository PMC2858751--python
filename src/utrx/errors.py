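"""Exception hierarchy.

``ValidationError`` covers malformed inputs and broken contracts (CLI exit
code 2); ``ComputationError`` covers conditions that make a requested
quantity undefined (CLI exit code 3).
"""


class UtrxError(Exception):
    """Base class for all package errors."""


class ValidationError(UtrxError):
    """Input data or configuration violates a documented contract."""


class MotifParseError(ValidationError):
    """Motif pattern text could not be parsed.

    Carries ``position``: the character offset in the pattern string at
    which parsing failed.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ComputationError(UtrxError):
    """A requested quantity is mathematically undefined for this input."""


class UndefinedCorrelationError(ComputationError):
    """Pearson correlation requested for a zero-variance profile."""
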