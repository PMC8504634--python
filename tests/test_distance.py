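"""Distance and decomposition: worked examples and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wassdd import (
    QuantileGrid,
    decompose,
    default_grid,
    empirical_quantiles,
    wasserstein_squared,
)

samples = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=1, max_size=60,
)


@pytest.mark.parametrize(
    "sample, grid, expected",
    [
        ([5], default_grid(7), [5] * 7),
        ([5], default_grid(1000), [5] * 1000),
        ([1, 2, 3], QuantileGrid(3, [1 / 6, 3 / 6, 5 / 6]), [1, 2, 3]),
        ([0, 0, 10], default_grid(6), [0, 0, 0, 0, 10, 10]),
    ],
)
def test_empirical_quantiles_examples(sample, grid, expected):
    np.testing.assert_array_equal(empirical_quantiles(sample, grid), expected)


def test_empirical_quantiles_rejects_empty_sample():
    with pytest.raises(ValueError, match="empty sample"):
        empirical_quantiles([], default_grid(10))


def test_quantile_grid_validation():
    with pytest.raises(ValueError):
        QuantileGrid(0)
    with pytest.raises(ValueError):
        QuantileGrid(3, [0.0, 0.5, 0.9])  # endpoint 0 not allowed
    with pytest.raises(ValueError):
        QuantileGrid(3, [0.5, 0.4, 0.9])  # not increasing


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2, 3], [2, 3, 4], 1.0),
        ([0, 0, 0, 0], [1, 1, 1, 1], 1.0),
    ],
)
def test_wasserstein_examples(a, b, expected):
    assert wasserstein_squared(a, b, default_grid(999)) == pytest.approx(expected, abs=1e-12)


def test_decompose_pure_shift():
    dc = decompose([1, 2, 3], [2, 3, 4], default_grid(999))
    assert dc.d == pytest.approx(1.0, abs=1e-12)
    assert dc.location == pytest.approx(1.0, abs=1e-12)
    assert dc.size == pytest.approx(0.0, abs=1e-12)
    assert dc.shape == pytest.approx(0.0, abs=1e-12)
    assert dc.rho == pytest.approx(1.0)
    assert dc.frac_location == pytest.approx(1.0, abs=1e-10)


def test_decompose_identical_samples_degenerate_fractions():
    dc = decompose([1, 2, 5], [1, 2, 5])
    assert dc.d == 0.0
    assert (dc.location, dc.size, dc.shape) == (0.0, 0.0, 0.0)
    assert (dc.frac_location, dc.frac_size, dc.frac_shape) == (0.0, 0.0, 0.0)
    assert dc.degenerate


def test_decompose_scale_change_hand_computation():
    # quantile vectors (0,2) and (0,4): means 1 vs 2, spreads 1 vs 2
    dc = decompose([0, 2], [0, 4], default_grid(1000))
    assert dc.location == pytest.approx(1.0, abs=1e-12)
    assert dc.sigma_a == pytest.approx(1.0)
    assert dc.sigma_b == pytest.approx(2.0)
    assert dc.size == pytest.approx(1.0, abs=1e-12)
    assert dc.rho == pytest.approx(1.0)
    assert dc.shape == pytest.approx(0.0, abs=1e-12)
    assert dc.d == pytest.approx(2.0, abs=1e-12)


def test_decompose_zero_spread_sample_flags_degenerate():
    dc = decompose([3, 3, 3], [1, 2, 9])
    assert dc.degenerate
    assert dc.rho == 1.0
    assert dc.shape == 0.0
    assert dc.d == pytest.approx(dc.location + dc.size, rel=1e-12)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(a=samples, b=samples)
def test_additivity_symmetry_and_rho_bounds(a, b):
    grid = default_grid(200)
    dc = decompose(a, b, grid)
    assert abs(dc.d - (dc.location + dc.size + dc.shape)) <= 1e-10 * max(1.0, dc.d)
    assert dc.location >= 0 and dc.size >= 0 and dc.shape >= 0
    assert 0.0 <= dc.rho <= 1.0
    assert wasserstein_squared(a, b, grid) == pytest.approx(
        wasserstein_squared(b, a, grid), rel=1e-12)
    if dc.d > 0:
        assert dc.frac_location + dc.frac_size + dc.frac_shape == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    data=st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=50),
    seed=st.integers(0, 10_000),
)
def test_sorted_pairs_oracle_for_equal_sizes(data, seed):
    """With n = m and n | K the distance equals the mean squared difference
    of the sorted samples (independent brute-force oracle)."""
    rng = np.random.default_rng(seed)
    n = len(data)
    a = np.array(data)
    b = rng.normal(scale=10, size=n)
    k = n * max(1, 600 // n)
    oracle = float(np.mean((np.sort(a) - np.sort(b)) ** 2))
    assert wasserstein_squared(a, b, default_grid(k)) == pytest.approx(
        oracle, abs=1e-12 * max(1.0, oracle))


def test_shift_moves_only_the_location_term(rng):
    a = rng.normal(size=80)
    b = np.sort(a) + 0.0  # same spread, rho = 1
    grid = default_grid(400)
    base = decompose(a, b, grid)
    shifted = decompose(a + 3.0, b, grid)
    assert shifted.size == pytest.approx(base.size, abs=1e-10)
    assert shifted.shape == pytest.approx(base.shape, abs=1e-10)
    assert shifted.location == pytest.approx(9.0, abs=1e-9)
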