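"""Shared fixtures: bundled datasets and their published corrected outputs."""

import numpy as np
import pytest

from midcorrect import datasets

# Percent-molar-enrichment outputs for the bundled example datasets, as
# printed at 2 decimal places in the original analyses.  Row order matches
# the labeled tables.
ACETYL_COA_EXPERIMENTAL = np.array([
    [68.63, -0.11, 32.86, -1.30, -0.10, 0.02],
    [67.68,  0.29, 33.48, -1.38, -0.10, 0.02],
    [68.50,  0.24, 32.84, -1.53, -0.06, 0.02],
])
ACETYL_COA_SIMULATED = np.array([
    [68.73, 2.22, 30.16,  0.09, -1.38, 0.18],
    [67.78, 2.59, 30.84,  0.01, -1.40, 0.18],
    [68.60, 2.57, 30.15, -0.15, -1.35, 0.18],
])
HMG_COA_EXPERIMENTAL = np.array([
    [52.29, -0.39, 35.12, 0.16, 12.41, -1.44, 1.86],
    [52.12,  0.09, 35.90, 0.50, 12.18, -2.03, 1.23],
    [51.70, -0.27, 36.06, 0.46, 11.69, -1.29, 1.65],
])
HMG_COA_SIMULATED = np.array([
    [51.29, 1.13, 33.91, 1.22, 11.83, -1.04, 1.66],
    [51.12, 1.61, 34.69, 1.57, 11.60, -1.62, 1.03],
    [50.71, 1.24, 34.84, 1.53, 11.12, -0.90, 1.46],
])
PROPIONATE = np.array([
    [36.13, 27.72, 31.24, 0.68, 1.72,  0.56,  1.94],
    [38.14, 23.24, 29.90, 6.55, 4.81, -2.07, -0.57],
    [36.17, 24.53, 32.42, 6.43, 3.37, -2.20, -0.72],
])


@pytest.fixture(scope="session")
def bundled():
    """All bundled tables, loaded once."""
    return {name: datasets.load(name) for name in datasets.available()}
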