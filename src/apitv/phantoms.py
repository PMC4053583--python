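"""Analytic ellipse phantoms (Shepp-Logan head phantom and variants).

A phantom is an ordered list of ellipses; the value at a point is the sum
of the intensities of all ellipses containing it, so overlapping ellipses
compose additively.  Coordinates are dimensionless fractions of the
half-field-of-view: the phantom lives in [-1, 1]^2 and is mapped onto the
pixel grid by :func:`rasterize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import yaml

from .grids import ImageGrid

__all__ = ["EllipseSpec", "PhantomSpec", "shepp_logan_spec", "rasterize"]


@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse: center and semi-axes as fractions of the half-FOV,
    rotation in degrees (counter-clockwise), additive intensity."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float
    intensity: float

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (boundary included)."""
        phi = np.deg2rad(self.rotation)
        c, s = np.cos(phi), np.sin(phi)
        dx = x - self.center_x
        dy = y - self.center_y
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / self.semi_axis_a) ** 2 + (v / self.semi_axis_b) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """An ordered, additive composition of ellipses."""

    ellipses: List[EllipseSpec]
    name: str = "phantom"

    def __post_init__(self) -> None:
        if len(self.ellipses) == 0:
            raise ValueError("phantom needs at least one ellipse")

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Analytic phantom value (sum of member intensities) at points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for e in self.ellipses:
            out += np.where(e.contains(x, y), e.intensity, 0.0)
        return out

    # -- plain-text serialization ------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "ellipses": [
                {
                    "center_x": e.center_x,
                    "center_y": e.center_y,
                    "semi_axis_a": e.semi_axis_a,
                    "semi_axis_b": e.semi_axis_b,
                    "rotation": e.rotation,
                    "intensity": e.intensity,
                }
                for e in self.ellipses
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        doc = yaml.safe_load(text)
        ellipses = [EllipseSpec(**d) for d in doc["ellipses"]]
        return cls(ellipses=ellipses, name=doc.get("name", "phantom"))


# Canonical Shepp-Logan ellipse table (Shepp & Logan 1974; tabulated form as
# in Toft's thesis / the MATLAB ``phantom`` function).  Columns:
# semi-axis a (x), semi-axis b (y), center x, center y, rotation (deg).
_SHEPP_LOGAN_GEOMETRY = [
    (0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.0230, 0.0460, 0.06, -0.6050, 0.0),
]

# Intensities by variant.  "standard" is the original low-contrast table.
# "high_contrast" keeps the geometry but raises the brain-feature
# intensities so the interior composes to exactly 1.0 and all features are
# visible in a [0.8, 1.2] display window (skull 2.0 ring, ventricles 0.8,
# small tumours 1.1).  "toft" is the widely used modified table (interior
# 0.2), included because library phantom generators ship it.
_INTENSITIES = {
    "standard": [2.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01],
    "high_contrast": [2.0, -1.0, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
    "toft": [1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
}


def shepp_logan_spec(variant: str = "high_contrast") -> PhantomSpec:
    """The canonical 10-ellipse Shepp-Logan head phantom.

    Parameters
    ----------
    variant : {"standard", "high_contrast", "toft"}
        ``standard`` is the original 1974 low-contrast table;
        ``high_contrast`` raises feature intensities for a [0.8, 1.2]
        display window; ``toft`` is the common "modified" table.
    """
    if variant not in _INTENSITIES:
        raise ValueError(
            f"unknown Shepp-Logan variant {variant!r}; "
            f"valid variants: {sorted(_INTENSITIES)}"
        )
    rho = _INTENSITIES[variant]
    ellipses = [
        EllipseSpec(
            center_x=x0,
            center_y=y0,
            semi_axis_a=a,
            semi_axis_b=b,
            rotation=phi,
            intensity=r,
        )
        for (a, b, x0, y0, phi), r in zip(_SHEPP_LOGAN_GEOMETRY, rho)
    ]
    return PhantomSpec(ellipses=ellipses, name=f"shepp-logan-{variant}")


def rasterize(
    spec: PhantomSpec,
    n: int,
    pixel_size: float = 1.0,
    supersample: int = 1,
) -> ImageGrid:
    """Rasterize a phantom onto an ``n x n`` grid spanning [-1, 1]^2.

    Pixel centers follow the symmetric convention: center of pixel
    ``(iy, ix)`` is at ``(-1 + (ix + 0.5) * 2/n, -1 + (iy + 0.5) * 2/n)``,
    with both coordinates increasing with the index.  By default each pixel
    takes the phantom value at its center (point sampling, no
    anti-aliasing); ``supersample=k`` averages a k x k subgrid per pixel
    for smoother edges.
    """
    if n < 2:
        raise ValueError("grid side length must be >= 2")
    if supersample < 1:
        raise ValueError("supersample factor must be >= 1")
    m = n * supersample
    step = 2.0 / m
    coords = -1.0 + (np.arange(m) + 0.5) * step
    x, y = np.meshgrid(coords, coords)  # y varies along axis 0
    img = spec.value_at(x, y)
    if supersample > 1:
        img = img.reshape(n, supersample, n, supersample).mean(axis=(1, 3))
    return ImageGrid(img, pixel_size=pixel_size)
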