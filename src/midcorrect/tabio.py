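"""Parsing, validation and writing of TSV/CSV intensity tables.

Input tables are pure numeric matrices — one row per sample, one column per
isotopologue, no headers, no sample-name column.  The most common entry
mistakes (pasted header rows, a missing cell, a trailing separator creating
an extra empty cell) are reported with the exact 1-based row and column of
the first offending cell, spreadsheet style, so the user can fix the cell
rather than hunt through the table.

The parser is deliberately hand-written: the coordinate-level error
contract is the whole point, and generic CSV readers do not surface cell
positions.  Only RFC-4180-style *unquoted* numeric fields are accepted;
intensity data never needs quoting, so a quoted field is treated as a
header-like non-numeric cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import EnrichmentMatrix, IntensityMatrix
from .errors import TableParseError

__all__ = [
    "TableParseReport",
    "parse_table",
    "validate_table",
    "report_dimensions",
    "write_table",
]

Dialect = Literal["tsv", "csv"]

_SEPARATORS = {"tsv": "\t", "csv": ","}

# spreadsheet exports and publisher renderings use U+2212 for the minus sign
_UNICODE_MINUS = "−"


@dataclass(frozen=True)
class TableParseReport:
    """Outcome of table validation: dimensions on success, coordinates on error.

    ``error_kind`` is one of ``none`` (status ok), ``non_numeric`` (a cell
    that does not parse as a finite number — typically a pasted header),
    ``malformed_row`` (a missing cell, an empty cell from a doubled or
    trailing separator, or extra cells), or ``invalid_intensity`` (a
    numeric but negative cell).  Coordinates are 1-based.
    """

    status: Literal["ok", "error"]
    n_rows: int = 0
    n_cols: int = 0
    error_kind: Literal["none", "non_numeric", "malformed_row", "invalid_intensity"] = "none"
    error_row: int | None = None
    error_col: int | None = None
    message: str = ""

    def __post_init__(self):
        if (self.status == "error") != (self.error_kind != "none"):
            raise ValueError("status and error_kind are inconsistent")
        if (self.status == "error") != (self.error_row is not None and self.error_col is not None):
            raise ValueError("error coordinates must be present exactly when status is error")


def _error(kind: str, row: int, col: int, message: str) -> TableParseReport:
    return TableParseReport(
        status="error", error_kind=kind, error_row=row, error_col=col, message=message
    )


def _parse_cell(cell: str) -> float | None:
    """Parse one cell to a finite float, or None if it is not numeric."""
    text = cell.strip().replace(_UNICODE_MINUS, "-")
    if not text or '"' in text:
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    if not np.isfinite(value):
        return None
    return value


def validate_table(text: str, dialect: Dialect = "tsv") -> TableParseReport:
    """Validate a table and return a structured report; never raises.

    On success the report carries the dimensions; on failure, the kind of
    problem and the 1-based row/column of the first cell that triggered it.
    """
    sep = _SEPARATORS[dialect]
    body = text.replace("\r\n", "\n").replace("\r", "\n")
    if body.endswith("\n"):
        body = body[:-1]  # a single trailing newline is not an extra row
    if not body.strip():
        return _error("malformed_row", 1, 1, "input is empty")

    lines = body.split("\n")
    n_cols = None
    values: list[list[float]] = []
    for r, line in enumerate(lines, start=1):
        cells = line.split(sep)
        if cells == [""]:
            return _error(
                "malformed_row", r, 1,
                f"malformed matrix: blank line at row {r}, column 1",
            )
        row_values: list[float] = []
        for c, cell in enumerate(cells, start=1):
            if cell.strip() == "":
                return _error(
                    "malformed_row", r, c,
                    f"malformed matrix: empty cell at row {r}, column {c} "
                    "(missing value or extra separator)",
                )
            value = _parse_cell(cell)
            if value is None:
                return _error(
                    "non_numeric", r, c,
                    f"non-numeric value at row {r}, column {c}: {cell.strip()!r}",
                )
            if value < 0:
                return _error(
                    "invalid_intensity", r, c,
                    f"negative signal intensity at row {r}, column {c}: {cell.strip()!r}",
                )
            row_values.append(value)
        if n_cols is None:
            n_cols = len(cells)
        elif len(cells) != n_cols:
            col = min(len(cells), n_cols) + 1
            return _error(
                "malformed_row", r, col,
                f"malformed matrix: row {r} has {len(cells)} cells but row 1 has {n_cols} "
                f"(problem at row {r}, column {col})",
            )
        values.append(row_values)

    return TableParseReport(status="ok", n_rows=len(values), n_cols=n_cols)


def parse_table(text: str, dialect: Dialect = "tsv") -> IntensityMatrix:
    """Parse a TSV/CSV numeric table into an :class:`IntensityMatrix`.

    Accepts plain decimals and scientific notation (``8.45E+07``); both the
    ASCII hyphen and the Unicode minus sign are recognized, and CRLF line
    endings are tolerated.  Raises :class:`TableParseError` carrying a
    :class:`TableParseReport` with 1-based cell coordinates on any
    validation failure.
    """
    report = validate_table(text, dialect)
    if report.status == "error":
        raise TableParseError(report)
    sep = _SEPARATORS[dialect]
    body = text.replace("\r\n", "\n").replace("\r", "\n")
    if body.endswith("\n"):
        body = body[:-1]
    rows = [
        [_parse_cell(cell) for cell in line.split(sep)]
        for line in body.split("\n")
    ]
    return IntensityMatrix(np.array(rows, dtype=float))


def report_dimensions(m: IntensityMatrix) -> str:
    """Dimension echo shown to the user on input, e.g. ``Data is 6 columns by 3 rows``."""
    return f"Data is {m.n_cols} columns by {m.n_rows} rows"


def write_table(
    m: EnrichmentMatrix | IntensityMatrix,
    dialect: Dialect = "tsv",
    precision: int = 2,
) -> str:
    """Format a matrix as TSV/CSV, fixed-point at ``precision`` decimals.

    One newline-terminated line per sample, no header, rows in input order
    — ready to paste back into a spreadsheet.
    """
    if precision < 0:
        raise ValueError("precision must be >= 0")
    sep = _SEPARATORS[dialect]
    return "".join(
        sep.join(f"{v:.{precision}f}" for v in row) + "\n" for row in m.values
    )
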