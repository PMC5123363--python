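# midcorrect

Natural-abundance correction of mass-spectrometry isotopologue intensities,
for stable-isotope tracer studies of metabolism.

In a tracer experiment (e.g. [¹³C₆]-glucose fed to cells), label
incorporation into a metabolite is read from the relative intensities of
its isotopologues M0, M+1, …, M+(n−1). Part of the heavy-isotopologue
signal comes not from the tracer but from naturally occurring heavy
isotopes (¹³C at ~1.1% per carbon, ²H, ¹⁵N, …), so raw intensities
overstate enrichment. `midcorrect` removes that background and reports
**percent molar enrichment** per isotopologue and sample.

## The model

Let f = (f₀, …, f₋₁) be the isotopologue distribution of the *unlabeled*
analyte — measured from unlabeled control replicates (recommended: column
means of the replicate table, normalized to sum to 1) or computed from the
elemental formula. The observed labeled row d_raw is modeled as

    d_raw = M_cor · x,        (M_cor)ᵢⱼ = f_{i−j}  for i ≥ j, else 0

where x holds the true mole quantities: a molecule that is truly M+j shows
up at M+(j+i) with probability fᵢ. M_cor is lower-triangular Toeplitz with
f₀ > 0 on the diagonal, so the system is solved exactly per sample row by
forward substitution (equivalent to x = M_cor⁻¹ · d_raw), and each solution
is rescaled to percentages of its algebraic row total:

    enrichmentᵢ = 100 · xᵢ / Σⱼ xⱼ

Rows sum to 100 by construction. Small negative entries are *kept* — they
are honest evidence of noise or interfering signals, and clipping or
penalizing them would hide data problems.

The matrix adapts to however many isotopologue columns were actually
measured; there is no requirement to pad the data out to the theoretical
series length.

## Worked example

The package bundles small example LC-MS datasets (see
`midcorrect.datasets`). Acetyl-CoA from [¹³C₆]-glucose-fed HeLa cells,
three unlabeled replicates and three labeled samples, six isotopologue
columns:

```python
from midcorrect import correct_dataset, datasets, write_table

unlabeled = datasets.load("acetyl_coa_unlabeled")
labeled = datasets.load("acetyl_coa_labeled")
print(write_table(correct_dataset(unlabeled, labeled), "tsv", 2), end="")
```

prints

```
68.63	-0.11	32.86	-1.30	-0.10	0.02
67.68	0.29	33.48	-1.38	-0.10	0.02
68.50	0.24	32.84	-1.53	-0.06	0.02
```

Each row is one labeled sample: ~68–69% of the acetyl-CoA pool is still
unlabeled (M0) and ~33% carries two glucose-derived ¹³C atoms (M2). Glucose
carbon enters acetyl-CoA in two-carbon units, so the odd isotopologues are
correctly near zero; their slightly negative values are measurement noise,
deliberately not clipped. Each row sums to 100.

The same pipeline is available from the shell:

```
midcorrect correct --unlabeled u.tsv --labeled l.tsv --precision 2
midcorrect simulate-background --formula C23H38N7O17P3S --n 6
midcorrect synthesize --series 0.9,0.08,0.02 --enrichment 0.6,0.1,0.3 \
    --noise-cv 0.02 --seed 17 --out-prefix sim
```

`correct` echoes the input dimensions ("Data is 6 columns by 3 rows") to
stderr and reports malformed input — a pasted header row, a trailing tab, a
ragged row — with the exact 1-based row and column of the offending cell.

More narrative examples are in `examples/`.

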