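"""Grid construction and raw/central/Hahn moment correctness.

The Hahn checks rely on independent oracles: term-by-term series evaluation
with plain Gamma-function Pochhammer products (no log-space stabilization),
a direct weighted-sum square norm, and brute-force double-loop moment sums.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from glycosite import moments as m

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def poch_oracle(a, k):
    prod = 1.0
    for i in range(k):
        prod *= a + i
    return prod


def hahn_oracle(n, r, N, u=0.0, v=0.0):
    """Direct evaluation: prefactor times the terminating 3F2 series."""
    pref = poch_oracle(N + v - 1, n) * poch_oracle(N - 1, n)
    total = 0.0
    for k in range(n + 1):
        num = (poch_oracle(-n, k) * poch_oracle(n + u + v + 1, k)
               * poch_oracle(-r, k))
        den = poch_oracle(u + 1, k) * poch_oracle(1 - N, k) * math.factorial(k)
        total += num / den
    return pref * total


def normalized_hahn_oracle(N, u=0.0, v=0.0, max_order=3):
    """h̃ values via the direct series, Gamma weight, and a summed norm."""
    def weight(r):
        return (math.gamma(u + r + 1) * math.gamma(v + N - r)
                / (math.gamma(r + 1) * math.gamma(N - r)))
    B = np.zeros((max_order + 1, N))
    for n in range(max_order + 1):
        d2 = sum(weight(r) * hahn_oracle(n, r, N, u, v) ** 2
                 for r in range(N))
        for r in range(N):
            B[n, r] = hahn_oracle(n, r, N, u, v) * math.sqrt(weight(r) / d2)
    return B


def brute_force_moments(grid, family):
    n = grid.shape[0]
    if family == "raw":
        return [sum(p ** i * q ** j * grid[p - 1, q - 1]
                    for p in range(1, n + 1) for q in range(1, n + 1))
                for i, j in m.MOMENT_ORDERS]
    if family == "central":
        m00 = grid.sum()
        xb = sum(p * grid[p - 1, q - 1] for p in range(1, n + 1)
                 for q in range(1, n + 1)) / m00
        yb = sum(q * grid[p - 1, q - 1] for p in range(1, n + 1)
                 for q in range(1, n + 1)) / m00
        return [sum((p - xb) ** i * (q - yb) ** j * grid[p - 1, q - 1]
                    for p in range(1, n + 1) for q in range(1, n + 1))
                for i, j in m.MOMENT_ORDERS]
    raise ValueError(family)


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

class TestReshape:
    def test_41mer_gives_7x7_with_8_trailing_zeros(self):
        grid = m.reshape_to_grid(np.arange(1, 42))
        assert grid.shape == (7, 7)
        assert grid.ravel()[41:].tolist() == [0.0] * 8
        assert grid.sum() == np.arange(1, 42).sum()

    def test_row_major_exact_fit(self):
        assert m.reshape_to_grid([1, 2, 3, 4]).tolist() == [[1, 2], [3, 4]]

    def test_singleton(self):
        assert m.reshape_to_grid([5]).tolist() == [[5]]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            m.reshape_to_grid([])

    @given(st.integers(1, 100))
    def test_dimension_is_ceil_sqrt(self, k):
        grid = m.reshape_to_grid(np.ones(k))
        n = grid.shape[0]
        assert (n - 1) ** 2 < k <= n ** 2


# ---------------------------------------------------------------------------
# raw & central moments
# ---------------------------------------------------------------------------

class TestRawCentral:
    def test_uniform_grid_known_values(self):
        ones = np.ones((7, 7))
        raw = m.raw_moments(ones)
        assert raw[(0, 0)] == 49
        assert raw[(1, 0)] == 196  # 7 * (1+...+7)
        assert raw[(0, 1)] == 196

    def test_zero_grid_all_raw_moments_zero(self):
        assert m.raw_moments(np.zeros((7, 7))).values == (0.0,) * 8

    def test_centroid_uniform_and_point_mass(self):
        assert m.centroid(m.raw_moments(np.ones((7, 7)))) == m.Centroid(4, 4)
        g = np.zeros((5, 5))
        g[1, 2] = 3.0  # 1-based grid coordinates (2, 3)
        c = m.centroid(m.raw_moments(g))
        assert (c.x, c.y) == (2, 3)

    def test_zero_grid_has_no_centroid(self):
        with pytest.raises(m.DegenerateGridError):
            m.centroid(m.raw_moments(np.zeros((3, 3))))
        with pytest.raises(m.DegenerateGridError):
            m.central_moments(np.zeros((3, 3)))

    def test_first_central_moments_vanish(self, rng):
        g = rng.integers(0, 21, size=(7, 7)).astype(float)
        cen = m.central_moments(g)
        assert cen[(1, 0)] == pytest.approx(0, abs=1e-9)
        assert cen[(0, 1)] == pytest.approx(0, abs=1e-9)
        assert cen[(0, 0)] == pytest.approx(m.raw_moments(g)[(0, 0)])

    def test_uniform_grid_eta11_zero(self):
        assert m.central_moments(np.ones((7, 7)))[(1, 1)] == pytest.approx(0)

    def test_point_mass_higher_central_moments_zero(self):
        g = np.zeros((6, 6))
        g[2, 4] = 7.0
        cen = m.central_moments(g)
        for i, j in m.MOMENT_ORDERS[1:]:
            assert cen[(i, j)] == pytest.approx(0, abs=1e-9)

    def test_translation_invariance_of_central_moments(self):
        pattern = np.array([[1.0, 2.0], [3.0, 4.0]])
        embeddings = []
        for (r0, c0) in [(0, 0), (3, 1), (5, 5)]:
            g = np.zeros((8, 8))
            g[r0:r0 + 2, c0:c0 + 2] = pattern
            embeddings.append(m.central_moments(g).as_array())
        keep = [idx for idx, (i, j) in enumerate(m.MOMENT_ORDERS) if i + j >= 2]
        for other in embeddings[1:]:
            np.testing.assert_allclose(embeddings[0][keep], other[keep],
                                       atol=1e-9)

    @pytest.mark.parametrize("size", [7, 20])
    def test_against_brute_force(self, size, rng):
        for _ in range(10):
            g = rng.integers(0, 21, size=(size, size)).astype(float)
            np.testing.assert_allclose(
                m.raw_moments(g).as_array(),
                brute_force_moments(g, "raw"), rtol=1e-12)
            np.testing.assert_allclose(
                m.central_moments(g).as_array(),
                brute_force_moments(g, "central"), rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# Hahn polynomials & moments
# ---------------------------------------------------------------------------

class TestHahn:
    def test_order_zero_is_one(self):
        for r in range(7):
            assert m.hahn_polynomial(0, r, 7) == pytest.approx(1.0)

    @pytest.mark.parametrize("u,v", [(0.0, 0.0), (1.0, 2.0), (0.5, 0.5)])
    def test_matches_direct_series_oracle(self, u, v):
        for N in (7, 20):
            for n in range(4):
                for r in range(N):
                    got = m.hahn_polynomial(n, r, N, u, v)
                    want = hahn_oracle(n, r, N, u, v)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_out_of_range_order_rejected(self):
        with pytest.raises(ValueError):
            m.hahn_polynomial(7, 0, 7)
        with pytest.raises(ValueError):
            m.hahn_polynomial(0, 7, 7)

    def test_weighted_orthogonality_low_orders(self):
        N = 7
        for a in range(4):
            for b in range(4):
                s = sum(m.hahn_weight(r, N) * m.hahn_polynomial(a, r, N)
                        * m.hahn_polynomial(b, r, N) for r in range(N))
                if a != b:
                    assert abs(s) < 1e-8 * math.sqrt(
                        m.hahn_norm_sq(a, N) * m.hahn_norm_sq(b, N))

    def test_basis_orthonormal(self):
        B = m.hahn_basis(7)
        np.testing.assert_allclose(B @ B.T, np.eye(7), atol=1e-8)

    def test_closed_form_norm_equals_direct_sum(self):
        for N in (7, 20):
            for n in range(min(N, 8)):
                direct = sum(m.hahn_weight(r, N)
                             * m.hahn_polynomial(n, r, N) ** 2
                             for r in range(N))
                assert m.hahn_norm_sq(n, N) == pytest.approx(direct, rel=1e-8)

    def test_full_order_reconstruction(self, rng):
        g = rng.integers(0, 21, size=(7, 7)).astype(float)
        H = m.hahn_transform(g)
        np.testing.assert_allclose(m.inverse_hahn_transform(H), g, atol=1e-6)

    def test_zero_grid_hahn_moments_zero(self):
        assert m.hahn_moments(np.zeros((7, 7))).values == (0.0,) * 8

    @pytest.mark.parametrize("size", [7, 20])
    def test_hahn_moments_against_double_loop_oracle(self, size, rng):
        B = normalized_hahn_oracle(size)
        g = rng.integers(0, 21, size=(size, size)).astype(float)
        got = m.hahn_moments(g)
        for i, j in m.MOMENT_ORDERS:
            want = sum(g[p, q] * B[i, p] * B[j, q]
                       for p in range(size) for q in range(size))
            assert got[(i, j)] == pytest.approx(want, rel=1e-9, abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(codes=arrays(np.int64, 41, elements=st.integers(1, 20)),
       data=st.data())
def test_moments_are_order_sensitive(codes, data):
    """Permuting a non-uniform window changes at least one of the 24 moments.

    Symmetric permutations can preserve individual families; the combined
    24-vector changing is the property relied on downstream.  Identity-like
    permutations (equal values swapped) are skipped.
    """
    grid = m.reshape_to_grid(codes)
    i = data.draw(st.integers(0, 40))
    j = data.draw(st.integers(0, 40))
    if codes[i] == codes[j]:
        return
    swapped = codes.copy()
    swapped[i], swapped[j] = swapped[j], swapped[i]
    grid2 = m.reshape_to_grid(swapped)
    combined = np.concatenate([
        m.raw_moments(grid).as_array(),
        m.central_moments(grid).as_array(),
        m.hahn_moments(grid).as_array()])
    combined2 = np.concatenate([
        m.raw_moments(grid2).as_array(),
        m.central_moments(grid2).as_array(),
        m.hahn_moments(grid2).as_array()])
    assert not np.allclose(combined, combined2)
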