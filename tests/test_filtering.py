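"""Temporal filter correctness against an independent direct-DFT oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinkhp import (
    DataError,
    FilterConfig,
    ImageStack,
    ParameterError,
    cutoff_index,
    highpass_filter_stack,
    highpass_filter_trace,
    median_filter_subtract,
    offset_to_nonnegative,
)


def dft_highpass_oracle(trace, omega_t):
    """O(T^2) high-pass via the explicit complex DFT matrix.

    Independent of the fast path: zeroes every full-spectrum bin whose
    absolute frequency index is below the cutoff (conjugate pairs included)
    and inverts by the conjugate-transpose matrix.
    """
    trace = np.asarray(trace, dtype=float)
    t = trace.size
    k_c = cutoff_index(t, omega_t)
    w = np.exp(-2j * np.pi * np.outer(np.arange(t), np.arange(t)) / t)
    spectrum = w @ trace
    abs_index = np.minimum(np.arange(t), t - np.arange(t))
    spectrum[abs_index < k_c] = 0.0
    return (w.conj().T @ spectrum).real / t


class TestCutoffIndex:
    @pytest.mark.parametrize(
        "n_frames, omega_t, expected",
        [(10, 0, 0), (10, 80, 4), (1, 50, 0), (10, 99.9, 5), (2000, 80, 800)],
    )
    def test_bin_arithmetic(self, n_frames, omega_t, expected):
        assert cutoff_index(n_frames, omega_t) == expected

    @pytest.mark.parametrize("omega_t", [-1, 100, 150])
    def test_domain(self, omega_t):
        with pytest.raises(ParameterError):
            cutoff_index(10, omega_t)

    @given(
        n=st.integers(1, 500),
        om1=st.floats(0, 99.99),
        om2=st.floats(0, 99.99),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, n, om1, om2):
        lo, hi = sorted([om1, om2])
        assert cutoff_index(n, lo) <= cutoff_index(n, hi)


class TestHighpassTrace:
    def test_constant_trace_annihilated(self):
        out = highpass_filter_trace(np.full(32, 7.5), 50)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_threshold_is_identity(self, rng):
        trace = rng.normal(100, 10, 57)
        np.testing.assert_allclose(highpass_filter_trace(trace, 0), trace)

    def test_passband_cosine_untouched(self):
        t, k0 = 50, 22  # k0 above the cutoff floor(0.8 * 26) = 20
        trace = np.cos(2 * np.pi * k0 * np.arange(t) / t)
        out = highpass_filter_trace(trace, 80)
        np.testing.assert_allclose(out, trace, rtol=0, atol=1e-9)

    @pytest.mark.parametrize("t", [1, 2, 3, 8, 17, 64])
    @pytest.mark.parametrize("omega_t", [0, 20, 50, 80, 95])
    def test_matches_direct_dft_oracle(self, rng, t, omega_t):
        trace = rng.normal(50, 20, t)
        expected = dft_highpass_oracle(trace, omega_t)
        np.testing.assert_allclose(
            highpass_filter_trace(trace, omega_t), expected, rtol=1e-9, atol=1e-9
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            highpass_filter_trace(np.array([1.0, np.nan, 2.0]), 50)


class TestStackFilter:
    def test_temporally_constant_stack_maps_to_zero(self, rng):
        pattern = rng.uniform(10, 1000, (5, 7))
        stack = ImageStack(np.broadcast_to(pattern, (40, 5, 7)).copy())
        out = highpass_filter_stack(stack, FilterConfig(80.0, "none"))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_zero_threshold_no_offset_is_identity(self, rng):
        stack = ImageStack(rng.normal(100, 5, (16, 4, 4)))
        out = highpass_filter_stack(stack, FilterConfig(0.0, "none"))
        np.testing.assert_allclose(out.data, stack.data)

    def test_single_frame_rejected(self):
        stack = ImageStack(np.ones((1, 4, 4)))
        with pytest.raises(ParameterError):
            highpass_filter_stack(stack, FilterConfig(50.0))

    def test_linearity(self, rng):
        a, b = 2.5, -1.25
        s1 = rng.normal(0, 10, (30, 3, 3))
        s2 = rng.normal(50, 5, (30, 3, 3))
        cfg = FilterConfig(60.0, "none")
        lhs = highpass_filter_stack(ImageStack(a * s1 + b * s2), cfg).data
        rhs = a * highpass_filter_stack(ImageStack(s1), cfg).data + (
            b * highpass_filter_stack(ImageStack(s2), cfg).data
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_idempotent_on_passband(self, rng):
        stack = ImageStack(rng.normal(100, 20, (50, 4, 4)))
        cfg = FilterConfig(70.0, "none")
        once = highpass_filter_stack(stack, cfg)
        twice = highpass_filter_stack(once, cfg)
        np.testing.assert_allclose(twice.data, once.data, rtol=1e-9, atol=1e-9)

    def test_energy_never_increases(self, rng):
        data = rng.normal(200, 30, (64, 5, 5))
        out = highpass_filter_stack(ImageStack(data), FilterConfig(40.0, "none"))
        pre = (data**2).sum(axis=0)
        post = (out.data**2).sum(axis=0)
        assert np.all(post <= pre + 1e-6)

    def test_metadata_preserved(self, rng):
        stack = ImageStack(rng.normal(0, 1, (8, 3, 3)), pixel_size=110.0,
                           frame_interval=8.0)
        out = highpass_filter_stack(stack, FilterConfig(50.0))
        assert out.pixel_size == 110.0 and out.frame_interval == 8.0

    def test_stack_matches_per_trace_filtering(self, rng):
        data = rng.normal(100, 10, (24, 3, 4))
        out = highpass_filter_stack(ImageStack(data), FilterConfig(75.0, "none"))
        for i in range(3):
            for j in range(4):
                np.testing.assert_allclose(
                    out.data[:, i, j],
                    highpass_filter_trace(data[:, i, j], 75.0),
                    rtol=1e-9, atol=1e-9,
                )


class TestOffset:
    def test_shift_to_zero_minimum(self):
        stack = ImageStack(np.array([[[-3.0, 0.0]], [[5.0, 1.0]]]))
        out = offset_to_nonnegative(stack)
        np.testing.assert_allclose(out.data, [[[0.0, 3.0]], [[8.0, 4.0]]])

    def test_all_zero_unchanged(self):
        stack = ImageStack(np.zeros((3, 2, 2)))
        np.testing.assert_allclose(offset_to_nonnegative(stack).data, 0.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_minimum_zero_and_constant_shift(self, seed):
        data = np.random.default_rng(seed).normal(0, 100, (4, 3, 3))
        out = offset_to_nonnegative(ImageStack(data)).data
        assert out.min() == 0.0
        shift = out - data
        np.testing.assert_allclose(shift, shift.flat[0])


class TestMedianSubtract:
    def test_constant_stack_zeroed(self):
        out = median_filter_subtract(ImageStack(np.full((10, 2, 2), 3.0)), 4)
        np.testing.assert_allclose(out.data, 0.0)

    def test_clamped_short_stack(self):
        trace = np.array([1.0, 1.0, 5.0, 1.0, 1.0]).reshape(-1, 1, 1)
        out = median_filter_subtract(ImageStack(trace), 2000)
        np.testing.assert_allclose(out.data.ravel(), [0, 0, 4, 0, 0])

    def test_rare_impulse_retains_height(self):
        trace = np.full(300, 10.0)
        trace[150:153] = 50.0  # 3-frame impulse on a long constant baseline
        out = median_filter_subtract(ImageStack(trace.reshape(-1, 1, 1)), 100)
        assert out.data[151, 0, 0] == pytest.approx(40.0)

    def test_edge_windows_clamped(self):
        # linear ramp: frame t has value t; window 4, half-window 2
        t_total = 10
        data = np.arange(t_total, dtype=float).reshape(-1, 1, 1)
        out = median_filter_subtract(ImageStack(data), 4).data.ravel()
        # first 2 frames use frames 0..3 (median 1.5), centred afterwards
        assert out[0] == pytest.approx(0 - 1.5)
        assert out[1] == pytest.approx(1 - 1.5)
        assert out[5] == pytest.approx(5 - np.median([3, 4, 5, 6]))
        # last frames use the final window 6..9 (median 7.5)
        assert out[9] == pytest.approx(9 - 7.5)
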