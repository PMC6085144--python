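"""Exception hierarchy for painlaw."""


class PainlawError(Exception):
    """Base class for all painlaw errors."""


class FormatError(PainlawError):
    """A table is structurally malformed (missing columns, unknown layout)."""


class ParseError(PainlawError):
    """A cell could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ValidationError(PainlawError):
    """Data violates a domain invariant."""


class DomainError(PainlawError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FitError(PainlawError):
    """A regression cannot be performed (too few usable points, etc.)."""
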