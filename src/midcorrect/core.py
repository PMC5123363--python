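"""Natural-abundance correction of isotopologue intensities.

Stable-isotope tracer experiments report, for each metabolite, a vector of
signal intensities over the isotopologues M0, M+1, ..., M+(n-1).  Part of
the signal in the heavier channels comes not from the tracer but from
naturally occurring heavy isotopes (¹³C at ~1.1%, ²H, ¹⁵N, ...).  Given the
isotopologue distribution of an *unlabeled* control — measured or
theoretical — the observed labeled intensities are modeled as

    d_raw = M_cor · x

where ``x`` holds the true mole quantities per isotopologue and ``M_cor``
is the lower-triangular Toeplitz matrix whose column j is the background
distribution shifted down j rows: a molecule that is truly M+j appears at
M+(j+i) with probability f_i, the background abundance of a +i natural
shift.  Correction solves the triangular system per sample row and rescales
the solution to percentages of its algebraic row total ("percent molar
enrichment"; rows sum to 100, small negative entries are kept as honest
evidence of noise).

This module is pure computation; parsing and formatting live in
:mod:`midcorrect.tabio`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular, toeplitz

from .errors import DegenerateRow, DimensionError, EmptyInput, SingularBackground

__all__ = [
    "IsotopologueSeries",
    "IntensityMatrix",
    "CorrectionMatrix",
    "EnrichmentMatrix",
    "average_replicates",
    "build_correction_matrix",
    "solve_correction",
    "percent_enrichment",
    "correct_dataset",
]


@dataclass(frozen=True)
class IsotopologueSeries:
    """Relative abundances f_0..f_{n-1} of an unlabeled analyte's isotopologues.

    ``values[i]`` is the relative abundance of the M+i isotopologue.  The
    M0 entry must be positive (otherwise the correction matrix would be
    singular); entries must be nonnegative.  When ``normalized`` is True the
    entries sum to 1 and the series reads as a probability distribution
    over natural mass shifts.
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise DimensionError("an isotopologue series must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise DimensionError("isotopologue series entries must be finite")
        if np.any(v < 0):
            raise DimensionError("isotopologue series entries must be nonnegative")
        if v[0] <= 0:
            raise SingularBackground(
                "the M0 abundance of the background series is zero; "
                "the correction matrix would be singular"
            )
        if self.normalized and abs(v.sum() - 1.0) > 1e-12:
            raise DimensionError("series flagged normalized must sum to 1 within 1e-12")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def normalize(self) -> "IsotopologueSeries":
        """Return the series rescaled to sum to 1."""
        s = self.values / self.values.sum()
        # guard against representation drift in the strict normalized check
        s = s / s.sum()
        return IsotopologueSeries(s, normalized=True)


@dataclass(frozen=True)
class IntensityMatrix:
    """Raw signal intensities: rows are samples, columns isotopologues M0..M+(n-1)."""

    values: np.ndarray
    row_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise EmptyInput("intensity matrix has no cells")
        if not np.all(np.isfinite(v)):
            raise DimensionError("intensity values must be finite")
        if np.any(v < 0):
            raise DimensionError("negative signal intensities are not valid input")
        if self.row_labels is not None and len(self.row_labels) != v.shape[0]:
            raise DimensionError("row_labels length must match the number of rows")
        object.__setattr__(self, "values", v)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular Toeplitz correction matrix built from a background series.

    Entry (i, j) equals ``source[i - j]`` for i >= j (zero once i - j runs
    past the series), so column j is the background distribution shifted
    down j rows.  Every diagonal entry equals the M0 abundance, hence the
    matrix is invertible whenever M0 > 0.
    """

    values: np.ndarray
    source: IsotopologueSeries

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EnrichmentMatrix:
    """Percent molar enrichment per sample (rows sum to 100; entries may be negative)."""

    values: np.ndarray
    row_labels: tuple[str, ...] | None = None

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def average_replicates(unlabeled: IntensityMatrix) -> IsotopologueSeries:
    """Collapse unlabeled replicate rows into one normalized background series.

    Raw intensities are averaged column-wise first and the mean vector is
    then rescaled to sum to 1.  Averaging raw intensities (rather than
    per-row normalized distributions) weights replicates by their signal,
    and is the behavior the bundled example datasets were produced with.

    Raises
    ------
    EmptyInput
        if the matrix has no rows.
    SingularBackground
        if the M0 column mean is zero.
    """
    means = unlabeled.values.mean(axis=0)
    if means[0] <= 0:
        raise SingularBackground(
            "mean M0 intensity of the unlabeled data is zero; cannot build a correction matrix"
        )
    return IsotopologueSeries(means).normalize()


def build_correction_matrix(series: IsotopologueSeries, n: int | None = None) -> CorrectionMatrix:
    """Build the n x n lower-triangular Toeplitz correction matrix.

    ``n`` defaults to the series length.  A longer series is truncated to
    the measured column count; a shorter one is implicitly zero-padded —
    the matrix adapts to the data dimensions rather than demanding the
    theoretical isotopologue-series length.
    """
    if n is None:
        n = len(series)
    if n < 1:
        raise DimensionError("matrix dimension must be at least 1")
    col = np.zeros(n)
    k = min(n, len(series))
    col[:k] = series.values[:k]
    if col[0] <= 0:
        raise SingularBackground("background series has zero M0 abundance")
    m = toeplitz(col, np.zeros(n))
    return CorrectionMatrix(m, source=series)


def solve_correction(m: CorrectionMatrix, raw_row: Sequence[float]) -> np.ndarray:
    """Solve M_cor · x = raw_row for the corrected mole quantities x.

    Equivalent to multiplying by the explicit inverse, but done by forward
    substitution on the triangular system for numerical stability.
    Negative components are retained unchanged.
    """
    row = np.asarray(raw_row, dtype=float)
    if row.ndim != 1 or row.size != m.n:
        raise DimensionError(
            f"raw row has {row.size} entries but the correction matrix is {m.n}x{m.n}"
        )
    if np.any(np.diag(m.values) == 0):
        raise SingularBackground("correction matrix has a zero diagonal entry")
    return solve_triangular(m.values, row, lower=True)


def percent_enrichment(corrected_row: Sequence[float], row_index: int = 1) -> np.ndarray:
    """Convert corrected mole quantities to percent molar enrichment.

    Each entry is divided by the algebraic sum of the row — negative
    components included — and multiplied by 100, so the output row sums to
    100 exactly in exact arithmetic.  ``row_index`` (1-based) is used only
    to name the sample in the degenerate-row error.
    """
    row = np.asarray(corrected_row, dtype=float)
    total = row.sum()
    if total == 0:
        raise DegenerateRow(row_index)
    return 100.0 * row / total


def correct_dataset(unlabeled: IntensityMatrix, labeled: IntensityMatrix) -> EnrichmentMatrix:
    """Full correction: unlabeled replicates + labeled samples -> percent enrichment.

    Composition of :func:`average_replicates`,
    :func:`build_correction_matrix`, and per-row :func:`solve_correction`
    followed by :func:`percent_enrichment`.  The output has the shape and
    row order of ``labeled``.

    Raises
    ------
    DimensionError
        if the two tables do not have the same column count.
    """
    if unlabeled.n_cols != labeled.n_cols:
        raise DimensionError(
            f"unlabeled data has {unlabeled.n_cols} columns but labeled data has "
            f"{labeled.n_cols}; both tables must have the same column dimension"
        )
    series = average_replicates(unlabeled)
    m = build_correction_matrix(series, labeled.n_cols)
    out = np.empty_like(labeled.values)
    for i, row in enumerate(labeled.values):
        out[i] = percent_enrichment(solve_correction(m, row), row_index=i + 1)
    return EnrichmentMatrix(out, row_labels=labeled.row_labels)
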