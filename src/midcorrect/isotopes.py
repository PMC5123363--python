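"""Theoretical natural-abundance isotopologue distributions.

Measured background distributions from unlabeled control samples are the
recommended input for correction — they capture instrument resolution and
matrix effects no simulation can.  When no unlabeled control exists but the
elemental formula is known, this module computes the theoretical
distribution instead: the isotopologue pattern aggregated by integer
(nominal) mass shift, obtained by convolving the per-atom shift
distributions of every atom in the formula.  Fine structure within one
nominal shift (e.g. one ¹³C versus one ²H) is deliberately merged, matching
how unit-resolution isotopologue series M0, M1, ... are tabulated.

Default isotopic abundances come from the NIST/IUPAC terrestrial values
shipped with :mod:`pyteomics` (¹³C at 1.07%).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from pyteomics.mass import nist_mass

from .core import IsotopologueSeries
from .errors import DimensionError, UnknownElement

__all__ = [
    "ElementalFormula",
    "IsotopeTable",
    "default_isotope_table",
    "theoretical_distribution",
    "truncation_loss",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts per element, e.g. ``{"C": 6, "H": 12, "O": 6}`` for glucose."""

    counts: Mapping[str, int]

    def __post_init__(self):
        if not self.counts:
            raise DimensionError("formula has no elements")
        for element, count in self.counts.items():
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise DimensionError(f"atom count for {element} must be a nonnegative integer")
        if all(count == 0 for count in self.counts.values()):
            raise DimensionError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(self.counts))

    @classmethod
    def from_string(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-style formula string like ``C23H38N7O17P3S``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise UnknownElement(f"cannot parse formula at {formula[pos:]!r}")
            pos = match.end()
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        if pos != len(formula) or not counts:
            raise UnknownElement(f"cannot parse formula {formula!r}")
        return cls(counts)


@dataclass(frozen=True)
class IsotopeTable:
    """Per element: (integer mass shift relative to the lightest isotope, abundance) pairs.

    Abundances for each element must be nonnegative and sum to 1; shifts
    are distinct nonnegative integers including 0.
    """

    isotopes: Mapping[str, Sequence[tuple[int, float]]]

    def __post_init__(self):
        for element, pairs in self.isotopes.items():
            shifts = [shift for shift, _ in pairs]
            abundances = np.array([a for _, a in pairs], dtype=float)
            if len(set(shifts)) != len(shifts) or any(s < 0 for s in shifts) or 0 not in shifts:
                raise DimensionError(
                    f"{element}: mass shifts must be distinct nonnegative integers including 0"
                )
            if np.any(abundances < 0) or abs(abundances.sum() - 1.0) > 1e-9:
                raise DimensionError(f"{element}: abundances must be >= 0 and sum to 1")

    def shift_pmf(self, element: str, n: int) -> np.ndarray:
        """Per-atom probability vector over shifts 0..n-1 (truncated, not renormalized)."""
        try:
            pairs = self.isotopes[element]
        except KeyError:
            raise UnknownElement(f"no isotope data for element {element!r}") from None
        pmf = np.zeros(n)
        for shift, abundance in pairs:
            if shift < n:
                pmf[shift] += abundance
        return pmf


def default_isotope_table() -> IsotopeTable:
    """Terrestrial-average abundances for all elements known to pyteomics."""
    isotopes: dict[str, list[tuple[int, float]]] = {}
    for element, table in nist_mass.items():
        mass_numbers = sorted(a for a, (_, abundance) in table.items() if a != 0 and abundance > 0)
        if not mass_numbers:
            continue
        lightest = mass_numbers[0]
        isotopes[element] = [(a - lightest, table[a][1]) for a in mass_numbers]
    return IsotopeTable(isotopes)


def _power_truncated(pmf: np.ndarray, k: int, n: int) -> np.ndarray:
    """k-fold self-convolution of pmf, truncated to length n (square-and-multiply)."""
    result = np.zeros(n)
    result[0] = 1.0
    base = pmf.copy()
    while k:
        if k & 1:
            result = np.convolve(result, base)[:n]
        k >>= 1
        if k:
            base = np.convolve(base, base)[:n]
    return result


def theoretical_distribution(
    formula: ElementalFormula | str,
    table: IsotopeTable | None = None,
    n: int = 6,
) -> IsotopologueSeries:
    """Theoretical isotopologue distribution of ``formula`` over shifts M0..M+(n-1).

    The distribution over the total integer mass shift is the convolution,
    across all atoms, of each atom's isotope-shift distribution; for a
    carbon-only formula this reduces to the binomial distribution over the
    ¹³C count.  The series is truncated at shift n-1 and NOT renormalized —
    the probability mass lost to truncation is available via
    :func:`truncation_loss` — so that normalization happens in exactly one
    place, the correction itself.
    """
    if n < 1:
        raise DimensionError("n must be at least 1")
    if isinstance(formula, str):
        formula = ElementalFormula.from_string(formula)
    if table is None:
        table = default_isotope_table()
    dist = np.zeros(n)
    dist[0] = 1.0
    for element, count in formula.counts.items():
        if count == 0:
            continue
        dist = np.convolve(dist, _power_truncated(table.shift_pmf(element, n), count, n))[:n]
    return IsotopologueSeries(dist, normalized=False)


def truncation_loss(series: IsotopologueSeries) -> float:
    """Probability mass beyond the truncated series (1 - sum of entries)."""
    return float(1.0 - series.values.sum())
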