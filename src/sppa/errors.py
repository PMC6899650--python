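"""Exception hierarchy for sppa."""


class SppaError(Exception):
    """Base class for all sppa errors."""


class FormatError(SppaError):
    """A required column or file section is missing or malformed."""


class ParseError(SppaError):
    """A value could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class InsufficientDataError(SppaError):
    """Too few observations for the requested operation."""


class UndefinedCurveError(SppaError):
    """A summary function is undefined for the given pattern (e.g. < 2 points)."""


class NoAggregationError(SppaError):
    """Cluster-model fitting requested but the observed curve never exceeds 1."""
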