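# Methods

## Correction model

An unlabeled analyte has an isotopologue distribution f = (f₀, …, f₋₁),
fᵢ being the fraction of molecules observed i nominal mass units above the
monoisotopic species. In a labeled sample, a molecule whose true tracer
shift is j is observed at shift j + i with probability fᵢ: natural isotope
incorporation is independent of tracer incorporation, and the natural
background of the tracer-substituted positions is assumed identical to that
of the unlabeled analyte. Under that assumption the observed intensity
vector is d_raw = M_cor · x with (M_cor)ᵢⱼ = f_{i−j} (i ≥ j), a
lower-triangular Toeplitz matrix, and correction is the triangular solve
followed by percent normalization of each row by its algebraic sum.

Assumptions worth stating:

- **Column count defines the model.** M_cor is n×n where n is the number of
  measured columns. Background mass at shifts ≥ n is simply outside the
  model (columns implicitly truncate); the user chooses the dimensions by
  choosing what to measure.
- **Negative solutions are retained.** They arise from noise and unresolved
  interferences. No clipping, penalty, or residuum is applied; percentage
  denominators include negative components, which is what makes output rows
  sum to exactly 100.
- **Averaging order.** Unlabeled replicate rows are averaged column-wise on
  the raw intensity scale, then the mean vector is normalized. This weights
  replicates by total signal; averaging per-row normalized distributions
  would weight them equally and gives different results when replicate
  totals differ. The bundled datasets reproduce their published outputs
  only under the raw-mean convention.
- **Normalization of f is cosmetic.** The output is invariant to rescaling
  f by any c > 0 (M_cor scales by c, the solution by 1/c, percentages
  cancel); f is normalized to sum to 1 only so it reads as a probability
  distribution.

## Numerical choices

- The triangular system is solved by forward substitution
  (`scipy.linalg.solve_triangular`) rather than forming M_cor⁻¹; the
  contract is identical (tests compare against the explicit-inverse oracle
  to 1e−10 relative) but substitution is numerically stabler.
- The only hard failure modes are structural: a zero M0 background mean
  (singular matrix), mismatched column counts, and a corrected row whose
  algebraic sum is exactly zero (percentages undefined; the error names the
  1-based sample row). Near-singular backgrounds (M0 mean tiny but nonzero)
  are not special-cased: the matrix condition number grows like
  max(f)/f₀ and the solve itself stays backward-stable, so garbage-in
  conditioning is surfaced as large output values rather than masked.
- Full double precision internally; formatting to a fixed number of
  decimals (default 2) happens only at output.

## Table validation

Input tables are headerless numeric matrices. The parser reports the first
problem with exact 1-based spreadsheet-style coordinates: `non_numeric` (a
pasted header or stray text), `malformed_row` (an empty cell from a doubled
or trailing separator, a blank line, or a row whose cell count differs from
row 1), and `invalid_intensity` (a negative raw intensity). Empty interior
cells are errors rather than implicit zeros — silent zero-filling would
mask exactly the data-selection mistakes the validation exists to catch.
Scientific notation, CRLF line endings, and the Unicode minus sign (U+2212,
common in spreadsheet exports and published tables) are accepted. CSV input
is RFC-4180 unquoted numerics; a quoted field is treated as non-numeric
since intensity data never needs quoting.

## Theoretical backgrounds

`theoretical_distribution` aggregates the isotope pattern by integer
(nominal) mass shift: the distribution of the total shift is the
convolution over all atoms of each atom's isotope-shift distribution,
computed per element by square-and-multiply self-convolution truncated at
shift n−1. For a carbon-only formula this is exactly the binomial
distribution over the ¹³C count. Fine structure within one nominal shift
(¹³C vs ²H) is deliberately merged — that is how unit-resolution
isotopologue series are tabulated. Truncated series are *not* renormalized;
the lost mass is reported by `truncation_loss`, keeping normalization in
exactly one place (the correction itself). Default abundances are the
NIST/IUPAC terrestrial values shipped with pyteomics (¹³C = 1.07%), which
pins them to a released library version.

Measured unlabeled controls are preferred over theoretical backgrounds
whenever available: relative isotopologue detection diverges from theory
with instrument resolution and sample-matrix effects, and the bundled
acetyl-CoA/HMG-CoA datasets show the simulated-background correction
misallocating ~2% enrichment into M1 where the experimental background puts
essentially none.

## Synthetic data generator

`synth.generate` runs the model forwards: unlabeled rows are f scaled to a
total intensity, labeled rows are M_cor · x scaled likewise, and every cell
is multiplied by (1 + ε), ε ~ Normal(0, noise_cv) i.i.d., clipped at −0.99
so intensities stay positive. Noise is multiplicative because MS signal
CVs scale roughly with intensity; additive detector noise, chromatographic
peak shape, saturation, and tracer impurity are *not* modeled. Passing
tests therefore demonstrate correctness of the algebra and graceful noise
propagation, not robustness to every instrument artifact. Defaults (three
unlabeled replicates, total intensity 10⁷ instrument units, noise_cv 0)
mirror a typical triplicate LC-MS design; noiseless generation must round-trip
to 1e−9, and at noise_cv = 0.02 with 100 samples the mean absolute M0
recovery error stays below one percentage point.

## Problem sizes and tolerances

Golden-value tests on the bundled datasets assert agreement within 0.05
absolute percentage points, the printed precision of the reference outputs
given 3-significant-figure inputs. Property tests run matrices up to
n = 10 (hypothesis, derandomized) — correction problems of realistic size
are this small, so nothing larger is informative. The acceptance script
uses 100 synthetic samples for the noise-recovery estimate.

## Known limitations

- One background per dataset: no per-sample backgrounds or interpolation.
- No tracer-purity correction, derivatization-group handling, or residuum
  scoring — deliberately out of scope; enrichment is measured above the
  natural background as-is.
- Theoretical patterns are nominal-mass only; exact-mass fine structure and
  resolution modeling are out of scope.
- Inputs are already-integrated intensities; no peak integration or vendor
  raw-format reading.
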