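"""Property-based invariants of the correction pipeline."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st

from midcorrect import (
    IntensityMatrix,
    IsotopologueSeries,
    build_correction_matrix,
    correct_dataset,
    solve_correction,
)

SETTINGS = dict(derandomize=True, max_examples=60, deadline=None)


@st.composite
def background_series(draw, max_n=8):
    """A plausible background: dominant M0 with a nonnegative tail."""
    n = draw(st.integers(min_value=1, max_value=max_n))
    m0 = draw(st.floats(min_value=0.5, max_value=1.0))
    tail = draw(
        st.lists(st.floats(min_value=0.0, max_value=0.3), min_size=n - 1, max_size=n - 1)
    )
    return IsotopologueSeries(np.array([m0, *tail]))


@st.composite
def dataset_pair(draw, max_n=6):
    """(unlabeled, labeled) with matching columns and non-degenerate rows."""
    n = draw(st.integers(min_value=1, max_value=max_n))
    pos = st.floats(min_value=1.0, max_value=1e6)
    small = st.floats(min_value=0.0, max_value=1e5)
    n_unl = draw(st.integers(min_value=1, max_value=3))
    n_lab = draw(st.integers(min_value=1, max_value=3))
    unl = [[draw(pos)] + [draw(small) for _ in range(n - 1)] for _ in range(n_unl)]
    lab = [[draw(pos)] + [draw(small) for _ in range(n - 1)] for _ in range(n_lab)]
    return IntensityMatrix(np.array(unl)), IntensityMatrix(np.array(lab))


@given(dataset_pair())
@settings(**SETTINGS)
def test_rows_sum_to_100(pair):
    """Percent molar enrichment conserves the row total by construction."""
    out = correct_dataset(*pair)
    np.testing.assert_allclose(out.values.sum(axis=1), 100.0, rtol=1e-9)


@given(dataset_pair(), st.floats(min_value=1e-3, max_value=1e3))
@settings(**SETTINGS)
def test_scale_invariance_of_unlabeled(pair, c):
    """Rescaling all unlabeled intensities cancels out of the percentages."""
    unlabeled, labeled = pair
    base = correct_dataset(unlabeled, labeled)
    scaled = correct_dataset(IntensityMatrix(unlabeled.values * c), labeled)
    np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9, atol=1e-9)


@given(dataset_pair(), st.floats(min_value=1e-3, max_value=1e3))
@settings(**SETTINGS)
def test_scale_invariance_of_labeled_rows(pair, c):
    """Rescaling a labeled row rescales the solve and cancels in the percentages."""
    unlabeled, labeled = pair
    base = correct_dataset(unlabeled, labeled)
    scaled = correct_dataset(unlabeled, IntensityMatrix(labeled.values * c))
    np.testing.assert_allclose(scaled.values, base.values, rtol=1e-9, atol=1e-9)


@given(dataset_pair())
@settings(**SETTINGS)
def test_identity_background_is_percent_passthrough(pair):
    """A pure-M0 background corrects nothing: output is the normalized input."""
    _, labeled = pair
    n = labeled.n_cols
    identity_bg = np.zeros((1, n))
    identity_bg[0, 0] = 1.0
    out = correct_dataset(IntensityMatrix(identity_bg), labeled)
    expected = 100.0 * labeled.values / labeled.values.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(out.values, expected, rtol=1e-12, atol=1e-12)


@given(st.integers(min_value=1, max_value=10), st.integers(min_value=0, max_value=2**31 - 1))
@settings(**SETTINGS)
def test_forward_substitution_matches_explicit_inverse(n, seed):
    """Triangular solve agrees with the brute-force inverse-multiply oracle."""
    rng = np.random.default_rng(seed)
    m = np.tril(rng.uniform(0.0, 1.0, size=(n, n)))
    np.fill_diagonal(m, rng.uniform(0.5, 1.5, size=n))
    row = rng.uniform(-10.0, 10.0, size=n)
    series = IsotopologueSeries(np.ones(1))  # placeholder source, values supplied directly
    from midcorrect.core import CorrectionMatrix

    x = solve_correction(CorrectionMatrix(m, series), row)
    oracle = np.linalg.inv(m) @ row
    np.testing.assert_allclose(x, oracle, rtol=1e-10, atol=1e-12)


@given(background_series(), st.data())
@settings(**SETTINGS)
def test_round_trip_recovery(series, data):
    """Correcting the forward-convolved enrichment recovers it exactly (no noise)."""
    n = len(series)
    raw = data.draw(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=n, max_size=n).filter(
            lambda v: sum(v) > 1e-3
        )
    )
    x = np.array(raw) / np.sum(raw)
    m = build_correction_matrix(series, n)
    observed = m.values @ x
    out = correct_dataset(
        IntensityMatrix(series.values.reshape(1, -1)),
        IntensityMatrix(observed.reshape(1, -1) * 1e6),
    )
    np.testing.assert_allclose(out.values[0], 100.0 * x, atol=1e-9)


@given(background_series(), st.integers(min_value=1, max_value=3))
@settings(**SETTINGS)
def test_self_correction_returns_pure_m0(series, n_rep):
    """Feeding the background back through the correction yields (100, 0, ..., 0)."""
    unlabeled = IntensityMatrix(np.tile(series.values * 1e6, (n_rep, 1)))
    out = correct_dataset(unlabeled, IntensityMatrix(series.values.reshape(1, -1)))
    expected = np.zeros(len(series))
    expected[0] = 100.0
    np.testing.assert_allclose(out.values[0], expected, atol=1e-9)
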