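"""Exception hierarchy.

All package errors derive from :class:`SigbnetError` so callers can catch
pipeline failures with a single ``except`` clause while still discriminating
between data-format problems, configuration mistakes and numerical failures.
"""


class SigbnetError(Exception):
    """Base class for all sigbnet errors."""


class TableFormatError(SigbnetError):
    """Input table violates the expected layout (columns, completeness)."""


class IntensityParseError(TableFormatError):
    """A non-numeric intensity was found; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ProteinLookupError(SigbnetError):
    """A requested protein is absent from the table or profile set."""

    def __init__(self, missing):
        self.missing = tuple(missing) if not isinstance(missing, str) else (missing,)
        super().__init__(f"protein(s) not found: {', '.join(self.missing)}")


class InsufficientDataError(SigbnetError):
    """Too few time points for the requested fit."""


class ConfigurationError(SigbnetError):
    """An option value is outside its admissible range or unknown."""


class GridAlignmentError(SigbnetError):
    """Profiles expected to share a time grid do not."""


class ExtrapolationError(SigbnetError):
    """Evaluation requested outside the measured time window."""


class IntegrationError(SigbnetError):
    """The ODE solver failed; carries the last successfully reached time."""

    def __init__(self, message: str, t_last: float | None = None):
        super().__init__(message)
        self.t_last = t_last


class MassBalanceError(SigbnetError):
    """An initial state violates the free + bound mass balances."""
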