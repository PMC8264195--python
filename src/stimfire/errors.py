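"""Exception hierarchy shared across the package."""


class StimfireError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(StimfireError, ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class ValidationError(StimfireError, ValueError):
    """Input data violate a schema or structural invariant.

    Carries optional ``row``/``column`` context so CLI users can locate
    the offending record in a CSV.
    """

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        if row is not None or column is not None:
            loc = ", ".join(
                part
                for part in (
                    f"row {row}" if row is not None else None,
                    f"column {column!r}" if column is not None else None,
                )
                if part
            )
            message = f"{message} ({loc})"
        super().__init__(message)


class DegenerateDataError(StimfireError, ValueError):
    """The data are degenerate for the requested statistic (e.g. zero baseline)."""
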