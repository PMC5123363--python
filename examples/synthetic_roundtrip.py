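"""Generate a synthetic tracer dataset with known truth and measure recovery.

The forward model convolves a chosen true enrichment with the correction
matrix and adds multiplicative noise; correcting the result should recover
the truth, with error that grows with the noise level.
"""

import numpy as np

from midcorrect import IsotopologueSeries, SyntheticSpec, correct_dataset, generate

truth_x = np.tile([0.6, 0.1, 0.3], (50, 1))
for noise_cv in (0.0, 0.02, 0.10):
    spec = SyntheticSpec(
        series=IsotopologueSeries([0.9, 0.08, 0.02]),
        true_enrichment=truth_x,
        noise_cv=noise_cv,
        n_unlabeled=3,
        seed=17,
    )
    unlabeled, labeled, truth = generate(spec)
    recovered = correct_dataset(unlabeled, labeled)
    mae = np.mean(np.abs(recovered.values - truth.values))
    print(f"noise_cv={noise_cv:4.2f}: mean |recovered - true| = {mae:.4f} percentage points")

print(
    "\nAt noise_cv=0 recovery is exact to rounding; the error scales with the\n"
    "noise, which is how replicate quality propagates into enrichment estimates."
)
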