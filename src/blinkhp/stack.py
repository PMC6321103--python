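"""Image-stack container shared by the filtering, simulation and localization code.

An :class:`ImageStack` is a ``T x H x W`` array of camera intensities (counts)
plus the pixel size in nanometres.  All spatial coordinates in this package are
expressed in nm with the origin at the image corner; pixel ``(i, j)`` covers the
half-open square ``[j*px, (j+1)*px) x [i*px, (i+1)*px)`` so that its centre sits
at ``((j+0.5)*px, (i+0.5)*px)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Default camera sampling: 16 um physical pixels behind a 100x objective.
DEFAULT_PIXEL_SIZE_NM = 160.0


class DataError(ValueError):
    """Raised when input data violate a documented contract."""


class ParameterError(ValueError):
    """Raised when a parameter is outside its documented domain."""


@dataclass
class ImageStack:
    """A time series of grayscale images.

    Parameters
    ----------
    data:
        ``(T, H, W)`` real-valued array of intensities in camera counts.
    pixel_size:
        Edge length of one pixel in nm.
    frame_interval:
        Optional time between frames in ms (metadata only).
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(
                f"stack data must be 3-D (T, H, W); got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise DataError(f"stack dimensions must all be >= 1; got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.number):
            raise DataError(f"stack dtype must be numeric; got {self.data.dtype}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("stack contains non-finite intensities")
        if not (self.pixel_size > 0):
            raise ParameterError(f"pixel_size must be > 0; got {self.pixel_size}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Return a new stack with the same metadata but different pixels."""
        return replace(self, data=data)
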