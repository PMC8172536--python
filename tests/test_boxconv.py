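"""Repeated-box convolution: coefficients, prefix sums, and the closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from scipy.integrate import quad

from fastnccc.boxconv import (beta_n, box_convolve, box_kernel_1d,
                              cumulative_stack, gamma_coefficients,
                              kernel_energy, window_sum)


class TestGammaCoefficients:
    @pytest.mark.parametrize("n, expected", [
        (0, [1]),
        (1, [-1, 0, 1]),
        (2, [1, 0, -2, 0, 1]),
    ])
    def test_known_tables(self, n, expected):
        assert gamma_coefficients(n).coeffs.tolist() == expected

    @given(st.integers(min_value=0, max_value=10))
    @settings(deadline=None, derandomize=True)
    def test_closed_form_equals_recursion(self, n):
        """The signed-Pascal closed form satisfies the two-term recursion."""
        table = gamma_coefficients(n)
        nxt = gamma_coefficients(n + 1)
        for k in range(-(n + 1), n + 2):
            assert nxt[k] == table[k - 1] - table[k + 1]

    @given(st.integers(min_value=0, max_value=10))
    @settings(deadline=None, derandomize=True)
    def test_parity_and_symmetry(self, n):
        table = gamma_coefficients(n)
        for k in range(-n, n + 1):
            if (n + k) % 2 == 1:
                assert table[k] == 0
            assert table[-k] == (-1) ** n * table[k]

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            gamma_coefficients(-1)


class TestCumulativeStack:
    def test_running_sum_1d(self):
        assert cumulative_stack(np.ones(3), 1).data.tolist() == [1, 2, 3]

    def test_double_sum_of_impulse_is_ramp(self):
        assert cumulative_stack(np.array([1.0, 0, 0]), 2).data.tolist() == [1, 2, 3]

    def test_matches_nested_summation_oracle(self, rng):
        """Order-2 stack equals brute-force summation over all lattice points
        dominated by the index in every axis."""
        f = rng.random((5, 4, 3))
        stack = cumulative_stack(f, 2)
        ref = np.zeros_like(f)
        for idx in np.ndindex(f.shape):
            for src in np.ndindex(f.shape):
                if all(s <= i for s, i in zip(src, idx)):
                    # multiplicity of an order-2 nested sum per axis
                    w = np.prod([i - s + 1 for s, i in zip(src, idx)])
                    ref[idx] += w * f[src]
        np.testing.assert_allclose(stack.data, ref, rtol=1e-12)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            cumulative_stack(np.array([1.0, np.nan]), 1)


class TestBoxKernel:
    @pytest.mark.parametrize("a, n", [(1, 1), (2, 2), (3, 2), (2, 3)])
    def test_taps_are_a_probability_kernel(self, a, n):
        taps = box_kernel_1d(a, n).taps
        assert len(taps) == 2 * n * a + 1
        assert taps.min() >= 0
        np.testing.assert_allclose(taps.sum(), 1.0, rtol=1e-12)
        np.testing.assert_allclose(taps, taps[::-1], rtol=1e-12)


class TestBoxConvolve:
    def test_dc_gain_is_one_in_interior(self):
        f = np.full((11, 11, 11), 0.5)
        out = box_convolve(f, 1, 2)
        np.testing.assert_allclose(out[4:-4, 4:-4, 4:-4], 0.5, rtol=1e-12)

    def test_impulse_gives_triangle(self):
        imp = np.zeros(11)
        imp[5] = 1.0
        out = box_convolve(imp, 1, 2)
        np.testing.assert_allclose(out[3:8], np.array([1, 2, 3, 2, 1]) / 9.0,
                                   rtol=1e-12)

    @pytest.mark.parametrize("a, n", [(1, 1), (2, 1), (3, 1), (4, 1),
                                      (1, 2), (2, 2), (3, 2),
                                      (1, 3), (2, 3)])
    def test_matches_direct_convolution(self, a, n, rng):
        """Closed-form prefix-sum convolution equals direct separable
        convolution with the explicit taps, to near machine precision."""
        shape = (15, 14, 13)
        f = rng.random(shape)
        out = box_convolve(f, a, n)
        ref = f.copy()
        taps = box_kernel_1d(a, n).taps
        for ax in range(3):
            ref = ndimage.correlate1d(ref, taps, axis=ax, mode="constant",
                                      cval=0.0)
        assert np.abs(out - ref).max() <= 1e-9

    def test_mass_conserved_for_zero_margin_input(self, rng):
        """With content away from the boundary, total mass is preserved."""
        f = np.zeros((13, 13, 13))
        f[5:8, 5:8, 5:8] = rng.random((3, 3, 3))
        out = box_convolve(f, 1, 2)
        np.testing.assert_allclose(out.sum(), f.sum(), rtol=1e-10)

    def test_symmetric_input_gives_symmetric_output(self, rng):
        f = rng.random((9, 9, 9))
        f = f + f[::-1, ::-1, ::-1]
        out = box_convolve(f, 1, 2)
        np.testing.assert_allclose(out, out[::-1, ::-1, ::-1], atol=1e-12)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            box_convolve(np.ones((5, 5, 5)), 3, 2)

    def test_mismatched_stack_rejected(self, rng):
        f = rng.random((9, 9, 9))
        stack = cumulative_stack(f, 1, margin=4)
        with pytest.raises(ValueError):
            box_convolve(f, 1, 2, stack=stack)


class TestKernelEnergy:
    def test_beta1_is_half(self):
        assert beta_n(1) == pytest.approx(0.5, abs=1e-12)

    def test_beta2_matches_quadrature(self):
        ref = quad(lambda w: np.sinc(w / np.pi) ** 4, -np.inf, np.inf,
                   limit=400)[0] / (2 * np.pi)
        assert beta_n(2) == pytest.approx(ref, abs=1e-6)

    def test_discrete_energy_equals_tap_enumeration(self):
        taps = box_kernel_1d(3, 2).taps
        assert kernel_energy(3, 2) == pytest.approx(float((taps ** 2).sum()),
                                                    abs=1e-15)

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_discrete_energy_converges_to_continuous(self, n):
        """a * kernel_energy(a, n) -> beta_n as a grows, monotonically closer."""
        errs = [abs(a * kernel_energy(a, n) - beta_n(n)) for a in (2, 8, 32)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-2  # convergence is O(1/a)


class TestWindowSum:
    def test_equals_brute_force_window_sum(self, rng):
        f = rng.random((9, 8, 7))
        w = 2
        got = window_sum(cumulative_stack(f, 1, margin=w + 1), w)
        fp = np.pad(f, w)
        ref = np.zeros_like(f)
        for idx in np.ndindex(f.shape):
            ref[idx] = fp[tuple(slice(i, i + 2 * w + 1) for i in idx)].sum()
        np.testing.assert_allclose(got, ref, rtol=1e-12)
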