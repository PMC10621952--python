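"""Exception hierarchy shared across the package.

Fatal errors abort a run (exit code 1 for configuration, 2 for data);
recoverable signals are consumed internally and surface as flagged rows
or warnings on standard error.
"""


class AnnotxError(Exception):
    """Base class for all package errors."""


class ParseError(AnnotxError):
    """Unrecoverable failure while parsing an annotation file.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(AnnotxError):
    """Invalid user configuration detected before annotation starts."""


class TableFormatError(AnnotxError):
    """Input interval table is unusable (e.g. mostly malformed rows)."""


class UnknownReferenceError(AnnotxError):
    """A reference (transcript ID) is absent from the database.

    Recoverable: the annotator emits the row with empty annotation.
    """


class OutOfRangeError(AnnotxError):
    """A coordinate falls outside the valid range for the operation."""


class InvalidIntervalError(AnnotxError):
    """An interval is empty or inverted under its declared convention."""
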