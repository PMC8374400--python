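"""Exception hierarchy shared by all ecoplant modules."""


class EcoplantError(Exception):
    """Base class for all errors raised by ecoplant."""


class InputFormatError(EcoplantError):
    """A file does not have the expected structure (missing/misplaced columns)."""


class ValidationError(EcoplantError):
    """A structurally valid file contains an invalid value; carries row context."""

    def __init__(self, message: str, *, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class DuplicateGenusError(ValidationError):
    """The same genus occurs more than once in one reference table."""


class ConfigurationError(EcoplantError):
    """A run was configured inconsistently (e.g. depth ordering without depths)."""
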