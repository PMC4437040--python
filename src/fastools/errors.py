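"""Exception hierarchy shared by all tools.

Usage errors (bad flags, malformed range or regex arguments) are raised before
any record is processed and map to exit status 1 on the command line; data
errors (malformed input records) map to exit status 2.
"""


class FastoolsError(Exception):
    """Base class for all package errors."""


class UsageError(FastoolsError):
    """Invalid configuration detected before processing begins."""


class ParseError(FastoolsError):
    """Malformed input data; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FieldResolutionError(FastoolsError):
    """A field address could not be resolved on a particular record."""
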