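"""Image container for reconstruction grids.

An :class:`ImageGrid` is a square pixel lattice with a physical pixel size
in mm.  The array index convention is ``data[iy, ix]`` with both physical
coordinates increasing with the index: pixel centers sit at

    x = (ix - (n - 1) / 2) * pixel_size
    y = (iy - (n - 1) / 2) * pixel_size

so row 0 is the *bottom* of the field of view.  Use ``np.flipud`` when
displaying with image viewers that put row 0 at the top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """A square image on a regular lattice with physical pixel size (mm)."""

    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError(f"image must be square 2D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n(self) -> int:
        """Side length in pixels."""
        return self.data.shape[0]

    @property
    def extent(self) -> float:
        """Physical side length of the field of view (mm)."""
        return self.n * self.pixel_size

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.data.copy(), self.pixel_size)

    def astype(self, dtype) -> "ImageGrid":
        return ImageGrid(self.data.astype(dtype), self.pixel_size)

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.data
        return self.data.astype(dtype)
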