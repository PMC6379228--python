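"""Exception types shared across the package."""


class GenemetaError(Exception):
    """Base class for all package errors."""


class SchemaError(GenemetaError):
    """A study table is missing required columns or is otherwise unreadable."""


class ValidationError(GenemetaError):
    """One or more rows of a study table failed validation.

    ``rows`` holds (1-based data row number, message) pairs when available.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows else []


class InsufficientStudiesError(GenemetaError):
    """An operation requires more studies than were supplied."""


class UndefinedEffectError(GenemetaError):
    """A 2x2 table has an empty margin, so no odds ratio is defined."""


class ConfigError(GenemetaError):
    """A simulation or analysis configuration is invalid."""
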