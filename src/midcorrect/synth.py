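"""Forward-model generator of synthetic tracer datasets with known truth.

Emulates the standard experimental design — a small group of unlabeled
replicate controls plus labeled samples with some true isotopologue
enrichment — by running the correction model forwards: an observed labeled
row is the correction matrix applied to the true mole-fraction vector,
scaled to instrument units, with multiplicative Gaussian noise per cell
(signal CVs in MS scale roughly with intensity, so noise is multiplicative,
not additive).  Because the truth is known, generated datasets exercise
every stage of the pipeline and quantify recovery error under noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    EnrichmentMatrix,
    IntensityMatrix,
    IsotopologueSeries,
    build_correction_matrix,
)
from .errors import SpecError

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    series
        true background distribution of the unlabeled analyte.
    true_enrichment
        one row per labeled sample; mole fractions >= 0 summing to 1.
    total_intensity
        scalar instrument-units scale applied to every row (arbitrary, the
        correction is scale invariant).
    noise_cv
        coefficient of variation of the multiplicative Gaussian noise,
        i.i.d. per cell; 0 gives noiseless tables.
    n_unlabeled
        number of unlabeled replicate rows (three replicates is the usual
        experimental recommendation).
    seed
        RNG seed; the same spec and seed give bit-identical tables.
    """

    series: IsotopologueSeries
    true_enrichment: np.ndarray
    total_intensity: float = 1e7
    noise_cv: float = 0.0
    n_unlabeled: int = 3
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.series, IsotopologueSeries):
            raise SpecError("series", "must be an IsotopologueSeries")
        x = np.atleast_2d(np.asarray(self.true_enrichment, dtype=float))
        if x.shape[1] != len(self.series):
            raise SpecError("true_enrichment", "column count must match the series length")
        if np.any(x < 0):
            raise SpecError("true_enrichment", "mole fractions must be nonnegative")
        if np.any(np.abs(x.sum(axis=1) - 1.0) > 1e-12):
            raise SpecError("true_enrichment", "each row must sum to 1 within 1e-12")
        if self.total_intensity <= 0:
            raise SpecError("total_intensity", "must be positive")
        if self.noise_cv < 0:
            raise SpecError("noise_cv", "must be nonnegative")
        if self.n_unlabeled < 1:
            raise SpecError("n_unlabeled", "must be at least 1")
        object.__setattr__(self, "true_enrichment", x)


def generate(spec: SyntheticSpec) -> tuple[IntensityMatrix, IntensityMatrix, EnrichmentMatrix]:
    """Generate (unlabeled, labeled, truth) tables from a :class:`SyntheticSpec`.

    Unlabeled rows are the background series scaled to ``total_intensity``;
    labeled rows are the forward-convolved true enrichment, M_cor · x,
    likewise scaled.  Each cell is multiplied by (1 + eps) with
    eps ~ Normal(0, noise_cv), clipped at -0.99 so intensities stay
    positive.  ``truth`` is the true enrichment in percent.
    """
    rng = np.random.default_rng(spec.seed)
    series = spec.series.normalize()
    f = series.values
    n = f.size
    m = build_correction_matrix(series, n).values
    x = spec.true_enrichment

    def noisy(clean: np.ndarray) -> np.ndarray:
        if spec.noise_cv == 0:
            return clean.copy()
        eps = np.clip(rng.normal(0.0, spec.noise_cv, size=clean.shape), -0.99, None)
        return clean * (1.0 + eps)

    unlabeled = noisy(np.tile(f * spec.total_intensity, (spec.n_unlabeled, 1)))
    labeled = noisy((x @ m.T) * spec.total_intensity)
    truth = EnrichmentMatrix(100.0 * x)
    return IntensityMatrix(unlabeled), IntensityMatrix(labeled), truth
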