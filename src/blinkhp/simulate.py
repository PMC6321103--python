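"""Ground-truth SMLM movie simulator.

Blinking single molecules are modelled as a two-state (on/off) alternating
renewal process with exponentially distributed sojourn times of mean
``tau_on`` and ``tau_off`` frames.  Emitters are placed uniformly inside a
region of interest at a prescribed surface density; every on-frame of an
emitter receives a fresh brightness draw from a lognormal distribution (mean
``B_mean`` counts per signal, SD ``sigma_B``, default ``B_mean/3``), rendered
as a pixel-integrated isotropic 2-D Gaussian of width ``sigma_psf`` (default
160 nm).  The rendered signals are added onto a background movie, either a
recorded stack or the synthetic autofluorescence model produced by
:func:`generate_synthetic_background`.

The synthetic background emulates the autofluorescence of a fungal hypha: a
spatially smooth bright band, nearly static in time.  Its per-pixel temporal
standard deviation is split into a dominant slow drift component (temporally
smooth, spatially coherent -- slow illumination/metabolic wander and
photobleaching-like variation) and a small fast white component representing
camera shot/readout noise on the bright baseline.  This mirrors real
autofluorescence movies, where frame-to-frame fluctuation is far smaller than
the drift accumulated over thousands of frames; it is the property that makes
temporal high-pass filtering effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import erf

from .stack import DEFAULT_PIXEL_SIZE_NM, DataError, ImageStack, ParameterError

__all__ = [
    "SimulationParams",
    "RoiMask",
    "TRUTH_COLUMNS",
    "sample_blink_intervals",
    "sample_blink_trace",
    "sample_positions",
    "sample_brightness",
    "render_gaussian_spot",
    "generate_synthetic_background",
    "simulate_movie",
]

#: Canonical ground-truth table schema (coordinates in nm, origin at corner).
TRUTH_COLUMNS = ("frame", "emitter_id", "x_nm", "y_nm", "counts")

_SQRT2 = math.sqrt(2.0)


@dataclass
class SimulationParams:
    """All knobs of the blinking-emitter simulation in one validated record.

    Units: counts for brightness, frames for sojourn times, emitters per um^2
    for density, nm for PSF width and pixel size.
    """

    b_mean: float = 750.0
    sigma_b: float | None = None  # None -> b_mean / 3
    tau_on: float = 3.0
    tau_off: float = 180.0
    density: float = 2.0
    sigma_psf: float = 160.0
    n_frames: int = 10_000
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    seed: int | None = None
    shot_noise: bool = False

    def __post_init__(self) -> None:
        if self.sigma_b is None:
            self.sigma_b = self.b_mean / 3.0
        checks = {
            "b_mean": self.b_mean > 0,
            "sigma_b": self.sigma_b >= 0,
            "tau_on": self.tau_on > 0,
            "tau_off": self.tau_off > 0,
            "density": self.density > 0,
            "sigma_psf": self.sigma_psf > 0,
            "n_frames": self.n_frames >= 1,
            "pixel_size": self.pixel_size > 0,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ParameterError(f"invalid simulation parameters: {', '.join(bad)}")


@dataclass
class RoiMask:
    """Binary region-of-interest mask (1 = inside the hypha/ROI)."""

    mask: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise DataError(f"ROI mask must be 2-D; got shape {self.mask.shape}")
        if not (self.pixel_size > 0):
            raise ParameterError("pixel_size must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size / 1000.0) ** 2


def sample_blink_intervals(
    tau_on: float,
    tau_off: float,
    n_frames: int,
    rng: np.random.Generator,
    initial_state: bool | None = None,
) -> list[tuple[float, float]]:
    """Simulate the continuous-time on/off process and return the on-intervals.

    The process alternates between on and off sojourns with exponential
    durations of mean ``tau_on`` and ``tau_off`` frames.  It is initialised in
    its stationary regime: the initial state is on with probability
    ``tau_on/(tau_on+tau_off)`` and, by memorylessness, the residual time of
    the first sojourn is again exponential.  Returned intervals ``(t0, t1)``
    are in frame units; the last one may extend past ``n_frames``, and an
    interval starting at exactly 0 is the truncated tail of an earlier sojourn.
    """
    if tau_on <= 0 or tau_off <= 0:
        raise ParameterError("tau_on and tau_off must be > 0")
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if initial_state is None:
        state = rng.random() < tau_on / (tau_on + tau_off)
    else:
        state = bool(initial_state)
    intervals: list[tuple[float, float]] = []
    t = 0.0
    while t < n_frames:
        duration = rng.exponential(tau_on if state else tau_off)
        if state:
            intervals.append((t, t + duration))
        t += duration
        state = not state
    return intervals


def sample_blink_trace(
    tau_on: float,
    tau_off: float,
    n_frames: int,
    rng: np.random.Generator,
    initial_state: bool | None = None,
) -> np.ndarray:
    """Binary on/off trace: frame ``i`` reports the state at time ``i``.

    Sampling the continuous-time process at integer times preserves the
    exponential sojourn statistics even for ``tau_on`` of order one frame.
    """
    states = np.zeros(n_frames, dtype=np.uint8)
    for t0, t1 in sample_blink_intervals(tau_on, tau_off, n_frames, rng, initial_state):
        i0 = int(math.ceil(t0))
        i1 = min(n_frames, int(math.ceil(t1)))
        if i1 > i0:
            states[i0:i1] = 1
    return states


def sample_positions(
    roi: RoiMask, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform emitter positions (nm) inside the ROI at the given density.

    The emitter count is the deterministic ``round(density * ROI area in
    um^2)``; each emitter lands in a uniformly chosen positive ROI pixel with
    continuous sub-pixel coordinates.  Returns an ``(n, 2)`` array of (x, y).
    """
    if density <= 0:
        raise ParameterError("density must be > 0")
    rows, cols = np.nonzero(roi.mask)
    if rows.size == 0:
        raise DataError("ROI mask has no positive pixels")
    n = int(round(density * roi.area_um2))
    if n == 0:
        return np.empty((0, 2))
    idx = rng.integers(0, rows.size, size=n)
    offsets = rng.random((n, 2))
    x = (cols[idx] + offsets[:, 0]) * roi.pixel_size
    y = (rows[idx] + offsets[:, 1]) * roi.pixel_size
    return np.column_stack([x, y])


def sample_brightness(
    b_mean: float, sigma_b: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal brightness draws with arithmetic mean/SD ``(b_mean, sigma_b)``.

    The underlying normal parameters are moment-matched:
    ``mu = ln(b_mean^2 / sqrt(b_mean^2 + sigma_b^2))`` and
    ``s^2 = ln(1 + sigma_b^2 / b_mean^2)``.  ``sigma_b = 0`` degenerates to a
    point mass at ``b_mean``.
    """
    if b_mean <= 0 or sigma_b < 0:
        raise ParameterError("need b_mean > 0 and sigma_b >= 0")
    if n < 0:
        raise ParameterError("n must be >= 0")
    if sigma_b == 0:
        return np.full(n, float(b_mean))
    ratio2 = (sigma_b / b_mean) ** 2
    mu = math.log(b_mean**2 / math.sqrt(b_mean**2 + sigma_b**2))
    s = math.sqrt(math.log1p(ratio2))
    return rng.lognormal(mean=mu, sigma=s, size=n)


def _axis_profile(center_nm: float, n_px: int, pixel_size: float, sigma: float) -> np.ndarray:
    """Per-pixel mass of a unit 1-D Gaussian integrated over pixel edges."""
    edges = np.arange(n_px + 1, dtype=np.float64) * pixel_size
    cdf = 0.5 * (1.0 + erf((edges - center_nm) / (sigma * _SQRT2)))
    return np.diff(cdf)


def render_gaussian_spot(
    x: float,
    y: float,
    counts: float,
    sigma_psf: float,
    shape: tuple[int, int],
    pixel_size: float,
) -> np.ndarray:
    """Pixel-integrated isotropic 2-D Gaussian spot.

    Pixel ``(i, j)`` receives the exact integral (via error-function
    differences) of a Gaussian of total mass ``counts``, centre ``(x, y)`` nm
    and width ``sigma_psf`` over the pixel's area.  The image sums to
    ``counts`` minus whatever mass falls outside the frame.
    """
    if counts < 0:
        raise ParameterError("counts must be >= 0")
    if sigma_psf <= 0:
        raise ParameterError("sigma_psf must be > 0")
    h, w = shape
    gy = _axis_profile(y, h, pixel_size, sigma_psf)
    gx = _axis_profile(x, w, pixel_size, sigma_psf)
    return counts * np.outer(gy, gx)


#: Number of independent temporal modes in the synthetic background drift.
_N_DRIFT_MODES = 8


def _slow_drift(
    shape: tuple[int, int, int],
    sd_map: np.ndarray,
    drift_timescale: float,
    spatial_corr_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow, spatially coherent drift with an exact per-pixel temporal SD.

    The drift is a sum of a few orthonormal slow temporal modes (zero-mean,
    unit-variance, Gaussian-smoothed over ``drift_timescale`` frames) with
    spatially smooth coefficient maps normalised to a unit vector per pixel.
    The per-pixel temporal variance is then exactly ``sd_map**2`` while every
    frame stays spatially smooth -- naive per-pixel rescaling of a smoothed
    random field would instead create sharp spatial sign boundaries.
    """
    t, h, w = shape
    n_modes = max(1, min(_N_DRIFT_MODES, t - 1))
    modes = gaussian_filter1d(
        rng.standard_normal((t, n_modes)), sigma=drift_timescale, axis=0,
        mode="reflect",
    )
    modes -= modes.mean(axis=0)
    q, _ = np.linalg.qr(modes)
    modes = q * math.sqrt(t)  # orthogonal, zero-mean, unit temporal variance
    coeff = rng.standard_normal((n_modes, h, w))
    if spatial_corr_px > 0:
        coeff = gaussian_filter(
            coeff, sigma=(0, spatial_corr_px, spatial_corr_px), mode="reflect"
        )
    norm = np.sqrt((coeff**2).sum(axis=0))
    norm[norm < 1e-12] = 1.0
    coeff = coeff / norm[None, :, :] * sd_map[None, :, :]
    return np.einsum("tj,jhw->thw", modes, coeff)


def _hypha_mask(
    shape: tuple[int, int], band_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """A thick, gently curved band across the frame, mimicking a hypha."""
    h, w = shape
    cols = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    amp = 0.08 * h
    center = 0.5 * h + amp * np.sin(2 * np.pi * cols / w * 0.8 + phase)
    half_width = 0.5 * band_fraction * h
    rows = np.arange(h)[:, None]
    return np.abs(rows - center[None, :]) <= half_width


def generate_synthetic_background(
    shape: tuple[int, int],
    n_frames: int,
    mean_level: float,
    temporal_std: float,
    bleach_tau: float = 50_000.0,
    rng: np.random.Generator | None = None,
    *,
    counts_per_photon: float = 0.1,
    drift_timescale: float = 150.0,
    band_fraction: float = 0.55,
    spatial_contrast: float = 0.15,
    spatial_corr_px: float = 10.0,
    texture_contrast: float = 0.02,
    texture_corr_px: float = 1.0,
    baseline: float = 100.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM,
) -> tuple[ImageStack, RoiMask]:
    """Synthetic autofluorescence movie of a hypha-like region.

    Inside a smooth band-shaped ROI, a spatially structured random field of
    mean ``mean_level`` evolves by a slow exponential decay of time constant
    ``bleach_tau`` frames plus a zero-mean temporal fluctuation whose per-pixel
    SD equals ``temporal_std``.  The static field has structure on two scales:
    a smooth large-scale modulation (relative SD ``spatial_contrast``,
    correlation ``spatial_corr_px``) and a fine-grained frozen texture
    (relative SD ``texture_contrast``, correlation ``texture_corr_px`` --
    about one PSF width), mimicking sub-resolution cellular granularity.  The
    texture is what makes unfiltered single-molecule detection on such samples
    so error-prone: static, spot-sized bumps are indistinguishable from real
    signals in a single frame, yet vanish entirely under temporal filtering.

    The temporal fluctuation is dominated by a slow, spatially coherent drift
    (Gaussian-smoothed over ``drift_timescale`` frames, normalised per pixel:
    slow illumination and metabolic wander of the kind that accumulates over
    thousands of frames); the fast per-frame component is shot noise on the
    detected intensity, with variance ``counts_per_photon x level`` per pixel
    (an sCMOS/EMCCD camera digitising at ``counts_per_photon`` camera counts
    per photon sees a photon shot-noise SD of exactly that form).  The slow
    SD is reduced so that the per-pixel total equals ``temporal_std`` inside
    the ROI.  Outside the ROI the autofluorescence is zero, but -- as on a
    real camera -- every pixel carries the constant bias ``baseline`` plus
    its shot noise.

    Returns the background stack and the ROI mask.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if mean_level <= 0:
        raise ParameterError("mean_level must be > 0")
    if temporal_std < 0:
        raise ParameterError("temporal_std must be >= 0")
    if counts_per_photon < 0:
        raise ParameterError("counts_per_photon must be >= 0")
    rng = np.random.default_rng(rng)
    h, w = shape
    mask = _hypha_mask(shape, band_fraction, rng)

    base = gaussian_filter(rng.standard_normal((h, w)), spatial_corr_px, mode="reflect")
    base /= max(base.std(), 1e-12)
    texture = gaussian_filter(rng.standard_normal((h, w)), texture_corr_px, mode="reflect")
    texture /= max(texture.std(), 1e-12)
    field = np.exp(spatial_contrast * base + texture_contrast * texture)
    # soften the band edge so the hypha boundary is not a hard step
    taper = gaussian_filter(mask.astype(np.float64), 3.0, mode="constant")
    field = field * taper
    field *= mean_level / field[mask].mean()

    if np.isfinite(bleach_tau):
        decay = np.exp(-np.arange(n_frames, dtype=np.float64) / bleach_tau)
    else:
        decay = np.ones(n_frames)
    movie = field[None, :, :] * decay[:, None, None]

    if temporal_std > 0:
        fast_var = counts_per_photon * (field * mask + baseline)
        slow_map = np.sqrt(np.maximum(temporal_std**2 - fast_var, 0.0)) * mask
        if n_frames > 1 and slow_map.any():
            movie += _slow_drift(
                (n_frames, h, w), slow_map, drift_timescale, spatial_corr_px, rng
            )
        movie *= mask[None, :, :]
        movie += baseline
        if counts_per_photon > 0:
            movie += rng.standard_normal(movie.shape) * np.sqrt(fast_var)[None, :, :]
    else:
        movie *= mask[None, :, :]
        movie += baseline
    return (
        ImageStack(movie, pixel_size=pixel_size),
        RoiMask(mask, pixel_size=pixel_size),
    )


def simulate_movie(
    params: SimulationParams,
    background: ImageStack,
    roi: RoiMask,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Overlay blinking emitters on a background movie.

    Emitter positions come from :func:`sample_positions`; each emitter gets an
    independent blink trace, and every on-frame receives a fresh lognormal
    brightness draw rendered with :func:`render_gaussian_spot` and added onto
    the corresponding background frame.  Returns the movie and the ground-truth
    table with one row per emitter per on-frame (columns
    ``frame, emitter_id, x_nm, y_nm, counts``).
    """
    if background.shape[1:] != roi.mask.shape:
        raise DataError(
            f"background frames {background.shape[1:]} do not match "
            f"ROI mask {roi.mask.shape}"
        )
    if background.n_frames < params.n_frames:
        raise DataError(
            f"background has {background.n_frames} frames; "
            f"{params.n_frames} required"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = params.n_frames
    h, w = roi.mask.shape
    movie = background.data[:t].astype(np.float64, copy=True)

    positions = sample_positions(roi, params.density, rng)
    records: list[np.ndarray] = []
    for emitter_id, (x, y) in enumerate(positions):
        trace = sample_blink_trace(params.tau_on, params.tau_off, t, rng)
        on_frames = np.nonzero(trace)[0]
        if on_frames.size == 0:
            continue
        counts = sample_brightness(params.b_mean, params.sigma_b, on_frames.size, rng)
        gy = _axis_profile(y, h, params.pixel_size, params.sigma_psf)
        gx = _axis_profile(x, w, params.pixel_size, params.sigma_psf)
        movie[on_frames] += counts[:, None, None] * np.outer(gy, gx)[None, :, :]
        records.append(
            np.column_stack(
                [
                    on_frames.astype(np.float64),
                    np.full(on_frames.size, float(emitter_id)),
                    np.full(on_frames.size, x),
                    np.full(on_frames.size, y),
                    counts,
                ]
            )
        )
    if records:
        table = pd.DataFrame(np.concatenate(records), columns=list(TRUTH_COLUMNS))
        table["frame"] = table["frame"].astype(int)
        table["emitter_id"] = table["emitter_id"].astype(int)
        table = table.sort_values(["frame", "emitter_id"], ignore_index=True)
    else:
        table = pd.DataFrame(
            {
                "frame": pd.Series(dtype=int),
                "emitter_id": pd.Series(dtype=int),
                "x_nm": pd.Series(dtype=float),
                "y_nm": pd.Series(dtype=float),
                "counts": pd.Series(dtype=float),
            }
        )
    if params.shot_noise:
        movie = rng.poisson(np.clip(movie, 0, None)).astype(np.float64)
    return background.with_data(movie), table
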