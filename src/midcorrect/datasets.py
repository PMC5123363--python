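"""Bundled example LC-MS isotopologue datasets.

Three small published-style example datasets ship with the package so the
full pipeline can be exercised without any external data:

``acetyl_coa`` and ``hmg_coa``
    MS2-fragment signal intensities of acetyl-CoA (6 isotopologue columns)
    and HMG-CoA (7 columns) from HeLa cells incubated 4 h in 25 mM
    [¹³C₆]-glucose, with three unlabeled-control replicates each, acquired
    on a Q Exactive in positive ESI mode.  Each also has a one-row
    instrument-simulated theoretical background ("simulated") for comparing
    experimental against theoretical normalization.

``propionate``
    MS/MS (SRM) intensities of an unknown product of propionate metabolism
    in HepG2 cells incubated with [²H₂]-propionate, 7 transitions
    (864→357 … 870→363), three unlabeled and three labeled samples — the
    metabolite-discovery use case where no theoretical background exists.
"""

from __future__ import annotations

from importlib import resources

from .core import IntensityMatrix
from .tabio import parse_table

__all__ = ["available", "load"]

_FILES = {
    "acetyl_coa_unlabeled": "acetyl_coa_unlabeled.tsv",
    "acetyl_coa_labeled": "acetyl_coa_labeled.tsv",
    "acetyl_coa_simulated": "acetyl_coa_simulated.tsv",
    "hmg_coa_unlabeled": "hmg_coa_unlabeled.tsv",
    "hmg_coa_labeled": "hmg_coa_labeled.tsv",
    "hmg_coa_simulated": "hmg_coa_simulated.tsv",
    "propionate_unlabeled": "propionate_unlabeled.tsv",
    "propionate_labeled": "propionate_labeled.tsv",
}


def available() -> list[str]:
    """Names accepted by :func:`load`."""
    return sorted(_FILES)


def load(name: str) -> IntensityMatrix:
    """Load a bundled table by name, e.g. ``load("acetyl_coa_unlabeled")``."""
    try:
        filename = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown dataset {name!r}; available: {', '.join(available())}") from None
    text = resources.files("midcorrect.data").joinpath(filename).read_text()
    return parse_table(text, dialect="tsv")
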