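"""Gram matrices, centering, and the HSIC^2 dependence measure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anmcausal.hsic import (
    HSICConfig,
    centering_matrix,
    gaussian_gram,
    hsic_squared,
    median_bandwidth,
)

FIXED = HSICConfig(bandwidth_mode="fixed", fixed_bandwidth=1.0)


def hsic_bruteforce(e, x, sigma_e, sigma_x):
    """Independent oracle: expand (1/m^2) Tr(K_E H K_X H) as the explicit
    double sum over index pairs of (H K_E H) entrywise with K_X."""
    m = len(e)
    ke = np.empty((m, m))
    kx = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            ke[i, j] = np.exp(-((e[i] - e[j]) ** 2) / (2 * sigma_e**2))
            kx[i, j] = np.exp(-((x[i] - x[j]) ** 2) / (2 * sigma_x**2))
    h = centering_matrix(m)
    ke_cent = h @ ke @ h
    total = 0.0
    for i in range(m):
        for j in range(m):
            total += ke_cent[i, j] * kx[j, i]
    return total / m**2


class TestMedianBandwidth:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ([0.0, 1.0], 1.0),          # single pairwise distance
            ([5.0, 5.0, 5.0], 1.0),     # degenerate fallback
            ([0.0, 1.0, 3.0], 2.0),     # median of {1, 3, 2}
        ],
    )
    def test_examples(self, v, expected):
        assert median_bandwidth(np.array(v)) == pytest.approx(expected)

    def test_requires_two_entries(self):
        with pytest.raises(ValueError):
            median_bandwidth(np.array([1.0]))

    def test_matches_enumeration(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=15)
        pairwise = [abs(v[i] - v[j]) for i in range(15) for j in range(i + 1, 15)]
        assert median_bandwidth(v) == pytest.approx(np.median(pairwise))


class TestGaussianGram:
    def test_single_point_is_one(self):
        np.testing.assert_allclose(gaussian_gram(np.array([7.3]), 2.0), [[1.0]])

    def test_identical_points_all_ones(self):
        np.testing.assert_allclose(gaussian_gram(np.zeros(3), 1.0), np.ones((3, 3)))

    def test_two_points(self):
        k = gaussian_gram(np.array([0.0, 1.0]), 1.0)
        assert k[0, 1] == pytest.approx(np.exp(-0.5))
        assert k[1, 0] == pytest.approx(np.exp(-0.5))

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            gaussian_gram(np.array([0.0, 1.0]), 0.0)

    def test_structure(self):
        rng = np.random.default_rng(1)
        k = gaussian_gram(rng.normal(size=20), 0.7)
        np.testing.assert_allclose(k, k.T)
        np.testing.assert_allclose(np.diag(k), 1.0)
        assert ((k > 0) & (k <= 1)).all()


class TestCenteringMatrix:
    def test_m1_is_zero(self):
        np.testing.assert_allclose(centering_matrix(1), [[0.0]])

    def test_m2(self):
        np.testing.assert_allclose(
            centering_matrix(2), [[0.5, -0.5], [-0.5, 0.5]]
        )

    def test_idempotent_and_zero_row_sums(self):
        h = centering_matrix(4)
        np.testing.assert_allclose(h @ h, h, atol=1e-12)
        np.testing.assert_allclose(h.sum(axis=1), 0.0, atol=1e-12)

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            centering_matrix(0)


class TestHSICSquared:
    def test_constant_residuals_give_zero(self):
        rng = np.random.default_rng(2)
        assert hsic_squared(np.full(10, 3.0), rng.normal(size=10)) <= 1e-12

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert hsic_squared(a, b) == pytest.approx(hsic_squared(b, a), abs=1e-14)

    def test_matches_bruteforce_fixed_bandwidth(self):
        rng = np.random.default_rng(4)
        e, x = rng.normal(size=6), rng.normal(size=6)
        expected = hsic_bruteforce(e, x, 1.0, 1.0)
        assert hsic_squared(e, x, FIXED) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_oracle_equivalence_small_m(self, m, seed):
        """Trace formula equals the explicit double-sum for all m <= 12."""
        rng = np.random.default_rng(seed)
        e, x = rng.normal(size=m), rng.normal(size=m) * 2.0
        cfg = HSICConfig()
        se, sx = median_bandwidth(e), median_bandwidth(x)
        expected = hsic_bruteforce(e, x, se, sx)
        assert hsic_squared(e, x, cfg) == pytest.approx(expected, abs=1e-10)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        e, x = rng.normal(size=30), rng.normal(size=30)
        base = hsic_squared(e, x, FIXED)
        assert hsic_squared(e + 17.0, x, FIXED) == pytest.approx(base, abs=1e-10)
        assert hsic_squared(e, x - 3.5, FIXED) == pytest.approx(base, abs=1e-10)

    def test_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            assert hsic_squared(rng.normal(size=15), rng.normal(size=15)) >= 0.0

    def test_detects_quadratic_dependence(self):
        """HSIC^2(x^2, x) should dominate HSIC^2(z, x) for independent z."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            z = rng.normal(size=200)
            if hsic_squared(x * x, x) > hsic_squared(z, x):
                wins += 1
        assert wins >= 19

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hsic_squared(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            hsic_squared(np.zeros(1), np.zeros(1))
        with pytest.raises(ValueError):
            HSICConfig(bandwidth_mode="fixed")
        with pytest.raises(ValueError):
            HSICConfig(bandwidth_mode="median", fixed_bandwidth=1.0)
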