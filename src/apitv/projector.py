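"""Forward projection and its exact adjoint for fan-beam geometries.

The projector computes discrete line integrals through the image with
exact ray/pixel intersection lengths (Siddon-style traversal).  Forward
and backprojection are matched operator pairs — the backprojector is the
exact transpose of the forward projector — which makes the ART data
projection well defined.  For small problems the full system matrix can
be assembled as a ``scipy.sparse`` matrix, mainly for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .geometry import ScanGeometry
from .grids import ImageGrid

__all__ = ["Sinogram", "forward_project", "back_project", "row_norms", "system_matrix"]


@dataclass
class Sinogram:
    """Projection data (line integrals, mm x attenuation) indexed
    ``(view, detector)``, with its generating geometry."""

    data: np.ndarray
    geom: ScanGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (self.geom.n_views, self.geom.n_det)
        if self.data.shape != expected:
            raise ValueError(
                f"sinogram shape {self.data.shape} inconsistent with geometry {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")

    def copy(self) -> "Sinogram":
        return Sinogram(self.data.copy(), self.geom)


def _check_image(img: ImageGrid, geom: ScanGeometry) -> None:
    if img.n != geom.image_n:
        raise ValueError(
            f"image side {img.n} does not match geometry image_n={geom.image_n}"
        )


def forward_project(img: ImageGrid, geom: ScanGeometry) -> Sinogram:
    """Line integrals of the image along every ray of the geometry.

    Each sinogram entry is the intersection-length-weighted sum of pixel
    values along the source-to-detector-element segment; rays that miss
    the grid give 0.
    """
    _check_image(img, geom)
    out = np.zeros((geom.n_views, geom.n_det))
    _kernels.forward_kernel(
        np.ascontiguousarray(img.data, dtype=np.float64),
        geom.angles,
        geom.sod,
        geom.sdd,
        geom.n_det,
        geom.det_pitch,
        geom.image_n,
        geom.pixel_size,
        out,
    )
    return Sinogram(out, geom)


def back_project(sino: Sinogram, geom: ScanGeometry | None = None) -> ImageGrid:
    """Exact adjoint of :func:`forward_project` (transposed weights)."""
    geom = geom or sino.geom
    if sino.data.shape != (geom.n_views, geom.n_det):
        raise ValueError("sinogram shape inconsistent with geometry")
    out = np.zeros((geom.image_n, geom.image_n))
    _kernels.back_kernel(
        np.ascontiguousarray(sino.data, dtype=np.float64),
        geom.angles,
        geom.sod,
        geom.sdd,
        geom.n_det,
        geom.det_pitch,
        geom.image_n,
        geom.pixel_size,
        out,
    )
    return ImageGrid(out, geom.pixel_size)


def row_norms(geom: ScanGeometry) -> np.ndarray:
    """Per-ray sums of squared intersection lengths, shape
    ``(n_views, n_det)``; zero for rays missing the grid."""
    out = np.zeros((geom.n_views, geom.n_det))
    _kernels.row_norms_kernel(
        geom.angles,
        geom.sod,
        geom.sdd,
        geom.n_det,
        geom.det_pitch,
        geom.image_n,
        geom.pixel_size,
        out,
    )
    return out


def system_matrix(geom: ScanGeometry, max_entries: int = 50_000_000) -> sp.csr_matrix:
    """Explicitly assembled system matrix, shape ``(n_rays, image_n**2)``.

    Intended for small problems and tests; entry weights are identical to
    the matrix-free operators.  Image pixels are flattened row-major
    (``iy * image_n + ix``).
    """
    n = geom.image_n
    cap = geom.n_rays * (3 * n + 4)
    if cap > max_entries:
        raise ValueError(
            f"system matrix would need up to {cap} entries; "
            "use the matrix-free operators for problems this large"
        )
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    vals = np.empty(cap, dtype=np.float64)
    cnt = _kernels.entries_kernel(
        geom.angles,
        geom.sod,
        geom.sdd,
        geom.n_det,
        geom.det_pitch,
        n,
        geom.pixel_size,
        rows,
        cols,
        vals,
    )
    A = sp.coo_matrix(
        (vals[:cnt], (rows[:cnt], cols[:cnt])), shape=(geom.n_rays, n * n)
    )
    return A.tocsr()
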