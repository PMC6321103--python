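"""Simulator statistics against renewal-theory and moment-matching oracles."""

import numpy as np
import pytest
from scipy import integrate

from blinkhp import (
    DataError,
    FilterConfig,
    ImageStack,
    ParameterError,
    RoiMask,
    SimulationParams,
    generate_synthetic_background,
    highpass_filter_stack,
    render_gaussian_spot,
    sample_blink_trace,
    sample_brightness,
    sample_positions,
    simulate_movie,
)
from blinkhp.simulate import sample_blink_intervals


class TestBlinkTrace:
    def test_forced_off_with_huge_tau_off(self, rng):
        trace = sample_blink_trace(5.0, 1e12, 500, rng, initial_state=False)
        assert trace.sum() == 0

    def test_invalid_rates(self, rng):
        with pytest.raises(ParameterError):
            sample_blink_trace(0.0, 10.0, 100, rng)

    def test_stationary_on_fraction(self, rng):
        # Monte-Carlo against the stationary occupancy tau_on/(tau_on+tau_off)
        tau_on, tau_off, n, reps = 5.0, 100.0, 1000, 10_000
        fractions = np.array(
            [sample_blink_trace(tau_on, tau_off, n, rng).mean() for _ in range(reps)]
        )
        expected = tau_on / (tau_on + tau_off)
        se = fractions.std(ddof=1) / np.sqrt(reps)
        assert abs(fractions.mean() - expected) < 3 * se

    def test_complete_on_sojourn_mean(self, rng):
        tau_on, tau_off, n = 5.0, 100.0, 1000
        durations = []
        for _ in range(4000):
            for t0, t1 in sample_blink_intervals(tau_on, tau_off, n, rng):
                if t0 > 0 and t1 < n:  # complete sojourns only
                    durations.append(t1 - t0)
        durations = np.asarray(durations)
        se = durations.std(ddof=1) / np.sqrt(durations.size)
        assert abs(durations.mean() - tau_on) < 3 * se


class TestPositions:
    def test_empty_roi_rejected(self, rng):
        with pytest.raises(DataError):
            sample_positions(RoiMask(np.zeros((4, 4))), 1.0, rng)

    def test_count_rule_and_containment(self, rng):
        roi = RoiMask(np.ones((100, 100)), pixel_size=160.0)  # 256 um^2
        pos = sample_positions(roi, 2.0, rng)
        assert pos.shape == (512, 2)
        assert np.all((pos >= 0) & (pos < 100 * 160.0))

    def test_vanishing_density_gives_no_emitters(self, rng):
        roi = RoiMask(np.ones((10, 10)), pixel_size=160.0)
        assert sample_positions(roi, 1e-6, rng).shape == (0, 2)


class TestBrightness:
    def test_degenerate_sigma(self, rng):
        np.testing.assert_array_equal(sample_brightness(600.0, 0.0, 5, rng), 600.0)

    def test_moment_matching(self, rng):
        b_mean, sigma_b, n = 750.0, 250.0, 100_000
        draws = sample_brightness(b_mean, sigma_b, n, rng)
        assert np.all(draws > 0)
        se_mean = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - b_mean) < 3 * se_mean
        # delta-method standard error for the sample SD
        dev = draws - draws.mean()
        m2, m4 = (dev**2).mean(), (dev**4).mean()
        se_sd = np.sqrt(max(m4 - m2**2, 0) / n) / (2 * np.sqrt(m2))
        assert abs(draws.std(ddof=1) - sigma_b) < 3 * se_sd


class TestRenderSpot:
    def test_zero_counts(self):
        img = render_gaussian_spot(800, 800, 0.0, 160.0, (10, 10), 160.0)
        np.testing.assert_array_equal(img, 0.0)

    def test_mass_conservation_interior(self):
        img = render_gaussian_spot(2000.0, 1800.0, 531.0, 160.0, (24, 24), 160.0)
        assert img.sum() == pytest.approx(531.0, rel=1e-6)

    def test_centroid_matches_centre(self):
        x, y, px = 1234.0, 1701.5, 160.0
        img = render_gaussian_spot(x, y, 1000.0, 160.0, (24, 24), px)
        rows, cols = np.mgrid[0:24, 0:24]
        cx = ((cols + 0.5) * px * img).sum() / img.sum()
        cy = ((rows + 0.5) * px * img).sum() / img.sum()
        assert abs(cx - x) < 0.01 * px
        assert abs(cy - y) < 0.01 * px

    def test_pixel_integral_matches_quadrature(self):
        x, y, sigma, px, counts = 700.0, 900.0, 160.0, 160.0, 1000.0
        img = render_gaussian_spot(x, y, counts, sigma, (12, 12), px)
        for i, j in [(5, 4), (6, 6)]:
            val, _ = integrate.dblquad(
                lambda xx, yy: np.exp(
                    -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
                ) / (2 * np.pi * sigma**2),
                i * px, (i + 1) * px,   # y limits (outer)
                j * px, (j + 1) * px,   # x limits (inner)
            )
            assert img[i, j] == pytest.approx(counts * val, rel=1e-8)


class TestSyntheticBackground:
    def test_static_when_noiseless(self, rng):
        bg, roi = generate_synthetic_background(
            (24, 24), 20, mean_level=500.0, temporal_std=0.0,
            bleach_tau=np.inf, rng=rng,
        )
        np.testing.assert_allclose(bg.data - bg.data[0], 0.0, atol=1e-9)
        assert roi.mask.sum() > 0

    def test_per_pixel_temporal_sd(self, rng):
        bg, roi = generate_synthetic_background(
            (32, 32), 2000, mean_level=1000.0, temporal_std=125.0,
            bleach_tau=np.inf, rng=rng,
        )
        sd = bg.data[:, roi.mask].std(axis=0)
        assert np.all(np.abs(sd - 125.0) / 125.0 < 0.10)

    def test_highpass_removes_most_background_variance(self, rng):
        bg, roi = generate_synthetic_background(
            (32, 32), 1000, mean_level=1000.0, temporal_std=125.0,
            bleach_tau=np.inf, rng=rng,
        )
        filtered = highpass_filter_stack(bg, FilterConfig(60.0, "none"))
        pre = bg.data[:, roi.mask].var(axis=0)
        post = filtered.data[:, roi.mask].var(axis=0)
        assert np.all(post / pre <= 0.45)


class TestSimulateMovie:
    def _background(self, n_frames=120, shape=(64, 64)):
        return ImageStack(np.zeros((n_frames, *shape)), pixel_size=160.0)

    def test_no_emitters_returns_background(self, rng, interior_roi):
        bg = self._background()
        params = SimulationParams(density=1e-9, n_frames=120, tau_on=3, tau_off=60)
        movie, truth = simulate_movie(params, bg, interior_roi, rng)
        np.testing.assert_array_equal(movie.data, bg.data)
        assert len(truth) == 0

    def test_occupancy_and_mass(self, rng, interior_roi):
        tau_on, tau_off, n_frames = 3.0, 30.0, 400
        params = SimulationParams(
            b_mean=500, tau_on=tau_on, tau_off=tau_off, density=1.0,
            n_frames=n_frames,
        )
        movie, truth = simulate_movie(params, self._background(n_frames), interior_roi, rng)
        n_emitters = int(round(1.0 * interior_roi.area_um2))
        expected_rows = n_frames * n_emitters * tau_on / (tau_on + tau_off)
        # binomial-style bound on the occupancy fluctuation
        se = np.sqrt(expected_rows)
        assert abs(len(truth) - expected_rows) < 4 * se
        assert movie.data.sum() == pytest.approx(truth["counts"].sum(), rel=1e-2)
        assert (truth["counts"] > 0).all()

    def test_truth_positions_inside_roi(self, rng, interior_roi):
        params = SimulationParams(density=2.0, n_frames=50, tau_on=3, tau_off=60)
        _, truth = simulate_movie(params, self._background(50), interior_roi, rng)
        cols = (truth["x_nm"] // 160).astype(int)
        rows = (truth["y_nm"] // 160).astype(int)
        assert interior_roi.mask[rows, cols].all()

    def test_fresh_brightness_each_on_frame(self, rng, interior_roi):
        params = SimulationParams(density=0.05, n_frames=400, tau_on=8, tau_off=40)
        _, truth = simulate_movie(params, self._background(400), interior_roi, rng)
        per_emitter = truth.groupby("emitter_id")["counts"].nunique()
        rows_per_emitter = truth.groupby("emitter_id").size()
        assert (per_emitter == rows_per_emitter).all()

    def test_reproducible_with_seed(self, interior_roi):
        params = SimulationParams(density=0.5, n_frames=60, tau_on=3, tau_off=60)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            movie, truth = simulate_movie(params, self._background(60), interior_roi, rng)
            out.append((movie, truth))
        np.testing.assert_array_equal(out[0][0].data, out[1][0].data)
        assert out[0][1].equals(out[1][1])

    def test_shape_mismatch_rejected(self, rng, interior_roi):
        params = SimulationParams(density=1.0, n_frames=10)
        with pytest.raises(DataError):
            simulate_movie(params, ImageStack(np.zeros((10, 8, 8))), interior_roi, rng)
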