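"""Exception types shared across the package."""


class PhytostressError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PhytostressError, ValueError):
    """A sample table violates the expected schema.

    Carries ``row`` (0-based data-row index, or None) so callers can point
    users at the offending record.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class DrudeDomainError(PhytostressError, ValueError):
    """Resistance or temperature outside the domain of the Drude relation."""


class UnknownEventKindError(PhytostressError, ValueError):
    """A stress event with an unrecognized kind."""
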