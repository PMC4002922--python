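"""Exception hierarchy.

Two families matter for exit codes: :class:`UsageError` (caller mistake,
CLI exit 2) and :class:`DataError` (malformed or inconsistent input, CLI
exit 1).
"""


class ViromekitError(Exception):
    """Base class for all package errors."""


class UsageError(ViromekitError):
    """The caller asked for something the API does not support."""


class DataError(ViromekitError):
    """Input data is malformed, inconsistent or out of range."""


class ParseError(DataError):
    """A text record could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlphabetError(DataError):
    """A sequence contains a character outside the DNA alphabet."""


class CoordinateError(DataError):
    """A feature lies outside its sequence."""


class MappingError(DataError):
    """An identifier could not be resolved to a known entity."""
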