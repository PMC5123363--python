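"""Exception hierarchy for midcorrect.

Every error a user can trigger from data (as opposed to programming
mistakes) derives from :class:`MidCorrectError`, so callers — notably the
CLI — can catch one type and print the message.
"""

from __future__ import annotations


class MidCorrectError(Exception):
    """Base class for all data-triggered errors."""


class EmptyInput(MidCorrectError):
    """An input table has no rows or no columns."""


class SingularBackground(MidCorrectError):
    """The M0 abundance of the background distribution is zero.

    The correction matrix is lower triangular with the M0 abundance on
    every diagonal entry, so a zero M0 makes it singular and the
    correction undefined.
    """


class DimensionError(MidCorrectError):
    """Shape mismatch between inputs that must agree."""


class DegenerateRow(MidCorrectError):
    """A corrected sample row sums to zero, so percentages are undefined.

    Carries the 1-based row index of the offending sample.
    """

    def __init__(self, row: int, message: str | None = None):
        self.row = row
        super().__init__(message or f"corrected intensities in sample row {row} sum to zero; "
                                    "percent molar enrichment is undefined")


class UnknownElement(MidCorrectError):
    """An elemental formula names an element missing from the isotope table."""


class SpecError(MidCorrectError):
    """A synthetic-data specification field is invalid.

    Carries the name of the offending field.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class TableParseError(MidCorrectError):
    """A table failed validation; carries the structured report."""

    def __init__(self, report):
        self.report = report
        super().__init__(report.message)
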