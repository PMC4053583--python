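"""Circular-trajectory fan-beam scan geometry.

Conventions (fixed; results are invariant to any internally consistent
choice):

* View 0 places the x-ray source on the +x axis at distance ``sod`` from
  the rotation axis (the isocenter, at the origin); rotation is
  counter-clockwise, so the source for view ``v`` sits at angle
  ``angles[v]``.
* The flat detector panel is perpendicular to the source--isocenter line
  at distance ``sdd`` from the source, elements centered about the panel
  midpoint.  Detector index 0 is at the panel edge with negative
  transaxial coordinate (the -w side, where ``w = (-sin θ, cos θ)``).
* The image spans ``image_n * pixel_size`` mm centered on the isocenter,
  with both pixel indices increasing with the physical coordinate (see
  :mod:`apitv.grids`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ScanGeometry",
    "default_sim_geometry",
    "ray_endpoints",
    "max_object_radius",
]


@dataclass
class ScanGeometry:
    """Circular fan-beam acquisition parameters (distances in mm)."""

    sod: float = 500.0
    sdd: float = 1000.0
    n_views: int = 60
    n_det: int = 512
    det_pitch: float = 1.0
    image_n: int = 256
    pixel_size: float = 1.0
    n_det_rows: int = 1
    angles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (0 < self.sod < self.sdd):
            raise ValueError("require 0 < sod < sdd")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.n_det < 1:
            raise ValueError("n_det must be >= 1")
        if self.det_pitch <= 0 or self.pixel_size <= 0:
            raise ValueError("det_pitch and pixel_size must be positive")
        if self.n_det_rows != 1:
            raise ValueError("only single-row (fan-beam) geometries are supported")
        if self.angles is None:
            self.angles = np.arange(self.n_views) * (2.0 * np.pi / self.n_views)
        else:
            self.angles = np.asarray(self.angles, dtype=float)
            if self.angles.shape != (self.n_views,):
                raise ValueError("angles must have length n_views")
            if np.any(np.diff(self.angles) <= 0):
                raise ValueError("angles must be strictly increasing")
            if self.angles[0] < 0 or self.angles[-1] >= 2.0 * np.pi:
                raise ValueError("angles must lie within [0, 2*pi)")

    # -- derived quantities -------------------------------------------------

    @property
    def n_rays(self) -> int:
        return self.n_views * self.n_det

    @property
    def fan_half_angle(self) -> float:
        """Half opening angle of the fan (radians)."""
        return float(np.arctan(0.5 * self.n_det * self.det_pitch / self.sdd))

    @property
    def magnification(self) -> float:
        return self.sdd / self.sod

    def with_views(self, n_views: int) -> "ScanGeometry":
        """Same geometry with a different (evenly spaced) view count."""
        return replace(self, n_views=n_views, angles=None)

    def source_position(self, view: int) -> np.ndarray:
        theta = self.angles[view]
        return self.sod * np.array([np.cos(theta), np.sin(theta)])

    def detector_position(self, view: int, det: int) -> np.ndarray:
        theta = self.angles[view]
        c, s = np.cos(theta), np.sin(theta)
        # panel center = source + sdd * (unit vector toward isocenter)
        center = (self.sod - self.sdd) * np.array([c, s])
        u = (det - (self.n_det - 1) / 2.0) * self.det_pitch
        return center + u * np.array([-s, c])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "sod": self.sod,
            "sdd": self.sdd,
            "n_views": self.n_views,
            "n_det": self.n_det,
            "det_pitch": self.det_pitch,
            "image_n": self.image_n,
            "pixel_size": self.pixel_size,
        }
        default = np.arange(self.n_views) * (2.0 * np.pi / self.n_views)
        if not np.allclose(self.angles, default):
            d["angles"] = [float(a) for a in self.angles]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        angles = d.pop("angles", None)
        if angles is not None:
            angles = np.asarray(angles, dtype=float)
        return cls(angles=angles, **d)


def default_sim_geometry() -> ScanGeometry:
    """The reference simulation geometry: 500 mm source radius, 1000 mm
    source-to-detector distance, 60 views evenly over 360 degrees, a
    512-element flat panel with 1 mm pitch, and a 256x256 image at
    1 mm pixels."""
    return ScanGeometry(
        sod=500.0,
        sdd=1000.0,
        n_views=60,
        n_det=512,
        det_pitch=1.0,
        image_n=256,
        pixel_size=1.0,
    )


def ray_endpoints(geom: ScanGeometry, view: int, det: int):
    """Source point and detector-element center (mm) for one ray.

    Raises ``IndexError`` for out-of-range view or detector indices.
    """
    if not (0 <= view < geom.n_views):
        raise IndexError(f"view {view} out of range [0, {geom.n_views})")
    if not (0 <= det < geom.n_det):
        raise IndexError(f"det {det} out of range [0, {geom.n_det})")
    return geom.source_position(view), geom.detector_position(view, det)


def max_object_radius(geom: ScanGeometry) -> float:
    """Radius (mm) of the largest isocentered disk seen by every ray fan.

    Objects inside this disk are fully sampled at every view; image pixels
    beyond it receive no data from some views.  At the default geometry the
    image corners lie outside this radius but the phantom support lies
    within it.
    """
    return geom.sod * np.sin(geom.fan_half_angle)
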