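"""Pixel-wise temporal filters for SMLM image stacks.

The core operation is a temporal high-pass in Fourier space, applied
independently to every pixel's time trace: the real-input spectrum of the trace
is computed, the bins below a threshold frequency ``omega_t`` are zeroed, and
the trace is transformed back.  A slowly varying background (autofluorescence,
out-of-focus light) lives almost entirely in the low-frequency bins and is
removed, while the on/off blinking of single molecules is broadband and
partially survives.  ``omega_t`` is expressed in percent of the non-negative
frequency axis: a trace of ``T`` frames has ``M = T//2 + 1`` non-negative
real-spectrum bins and the ``floor(omega_t/100 * M)`` lowest ones are zeroed.
``omega_t = 0`` therefore leaves the trace untouched, and any ``omega_t`` large
enough to zero at least the DC bin maps a temporally constant trace to exactly
zero.

A sliding-window temporal median subtraction is provided as the conventional
baseline against which the Fourier filter is compared.

Because each pixel is filtered over its *entire* time trace, processing can be
chunked over pixels but never streamed frame by frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stack import DataError, ImageStack, ParameterError

__all__ = [
    "FilterConfig",
    "cutoff_index",
    "highpass_filter_trace",
    "highpass_filter_stack",
    "offset_to_nonnegative",
    "median_filter_subtract",
]

#: Block size (in pixels) for chunked whole-stack FFTs, to bound peak memory.
_CHUNK_PIXELS = 1 << 20


@dataclass
class FilterConfig:
    """Settings for :func:`highpass_filter_stack`.

    ``omega_t`` is the high-pass threshold in percent of the non-negative
    frequency axis, in ``[0, 100)``.  ``offset_mode`` controls what happens
    after filtering: ``"global_min_to_zero"`` shifts the whole sequence by a
    single scalar so its minimum is exactly zero (avoiding negative pixel
    values), ``"none"`` leaves the zero-mean traces as they are.
    """

    omega_t: float = 80.0
    offset_mode: str = "global_min_to_zero"

    def __post_init__(self) -> None:
        if not (0 <= self.omega_t < 100):
            raise ParameterError(f"omega_t must be in [0, 100); got {self.omega_t}")
        if self.offset_mode not in ("global_min_to_zero", "none"):
            raise ParameterError(f"unknown offset_mode {self.offset_mode!r}")


def cutoff_index(n_frames: int, omega_t: float) -> int:
    """Number of low-frequency bins to zero for a trace of ``n_frames``.

    Returns ``k_c = floor(omega_t/100 * M)`` with ``M = n_frames//2 + 1`` the
    number of non-negative real-spectrum bins; bins ``k < k_c`` are zeroed.
    ``k_c = 0`` means no filtering.
    """
    if n_frames < 1:
        raise ParameterError(f"n_frames must be >= 1; got {n_frames}")
    if not (0 <= omega_t < 100):
        raise ParameterError(f"omega_t must be in [0, 100); got {omega_t}")
    m = n_frames // 2 + 1
    return int(math.floor(omega_t / 100.0 * m))


def highpass_filter_trace(trace: np.ndarray, omega_t: float) -> np.ndarray:
    """High-pass filter a single intensity trace.

    The trace's real-input spectrum is computed, bins below
    :func:`cutoff_index` are zeroed, and the inverse transform is returned.
    Output length equals input length; output is real; no offset is applied.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise DataError(f"trace must be 1-D; got shape {trace.shape}")
    if not np.all(np.isfinite(trace)):
        raise DataError("trace contains non-finite values")
    n = trace.shape[0]
    k_c = cutoff_index(n, omega_t)
    if k_c == 0:
        return trace.copy()
    spectrum = np.fft.rfft(trace)
    spectrum[:k_c] = 0.0
    return np.fft.irfft(spectrum, n=n)


def offset_to_nonnegative(stack: ImageStack) -> ImageStack:
    """Shift the whole sequence by one scalar so that its minimum is zero.

    A single global offset (the negative of the minimum over all pixels and
    frames) is added to every pixel, preserving all relative differences.
    """
    if stack.data.size == 0:
        raise DataError("cannot offset an empty stack")
    return stack.with_data(stack.data - stack.data.min())


def highpass_filter_stack(stack: ImageStack, cfg: FilterConfig) -> ImageStack:
    """Apply the temporal high-pass to every pixel of a stack.

    Each pixel's time trace is filtered with :func:`highpass_filter_trace`
    (vectorised over pixels, computed in double precision) and, when
    ``cfg.offset_mode == "global_min_to_zero"``, the whole result is shifted so
    its minimum is zero.  Metadata is preserved.
    """
    t = stack.n_frames
    if cfg.omega_t > 0 and t == 1:
        raise ParameterError("cannot high-pass filter a single-frame stack")
    k_c = cutoff_index(t, cfg.omega_t)
    data = stack.data.astype(np.float64, copy=False)
    if k_c == 0:
        out = data.astype(np.float64, copy=True)
    else:
        flat = data.reshape(t, -1)
        out = np.empty_like(flat)
        for start in range(0, flat.shape[1], _CHUNK_PIXELS):
            block = flat[:, start : start + _CHUNK_PIXELS]
            spectrum = np.fft.rfft(block, axis=0)
            spectrum[:k_c] = 0.0
            out[:, start : start + _CHUNK_PIXELS] = np.fft.irfft(spectrum, n=t, axis=0)
        out = out.reshape(stack.shape)
    result = stack.with_data(out)
    if cfg.offset_mode == "global_min_to_zero":
        result = offset_to_nonnegative(result)
    return result


def median_filter_subtract(stack: ImageStack, window: int = 2000) -> ImageStack:
    """Subtract a sliding-window temporal median from every frame.

    For frame ``t`` the per-pixel median over a ``window``-frame block centred
    at ``t`` is subtracted.  Near the edges the block is clamped: the first
    ``window//2`` frames all use the first ``window`` frames, the last
    ``window//2`` use the last ``window``.  If the sequence is no longer than
    the window, the median over all frames is used throughout.
    """
    if window < 1:
        raise ParameterError(f"window must be >= 1; got {window}")
    data = stack.data.astype(np.float64, copy=False)
    t_total = stack.n_frames
    width = min(window, t_total)
    out = np.empty_like(data)
    half = window // 2
    medians: dict[int, np.ndarray] = {}
    for t in range(t_total):
        start = min(max(t - half, 0), t_total - width)
        if start not in medians:
            medians[start] = np.median(data[start : start + width], axis=0)
        out[t] = data[t] - medians[start]
    return stack.with_data(out)
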