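"""Reading and writing images, sinograms and configs.

Images and sinograms are stored as 32-bit float TIFF; a sinogram carries
a YAML sidecar (``<name>.geom.yaml``) describing its scan geometry, so no
bespoke binary format is needed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import ScanGeometry
from .grids import ImageGrid
from .projector import Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
    "save_config",
    "load_config",
]


def save_image(path, img: ImageGrid) -> None:
    tifffile.imwrite(str(path), np.asarray(img.data, dtype=np.float32))


def load_image(path, pixel_size: float = 1.0) -> ImageGrid:
    return ImageGrid(tifffile.imread(str(path)).astype(np.float64), pixel_size)


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".geom.yaml")


def save_sinogram(path, sino: Sinogram) -> None:
    tifffile.imwrite(str(path), np.asarray(sino.data, dtype=np.float32))
    _sidecar(path).write_text(yaml.safe_dump(sino.geom.to_dict(), sort_keys=False))


def load_sinogram(path) -> Sinogram:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sinogram geometry sidecar {sidecar} not found; sinograms are "
            "stored as TIFF + <name>.geom.yaml"
        )
    geom = ScanGeometry.from_dict(yaml.safe_load(sidecar.read_text()))
    return Sinogram(tifffile.imread(str(path)).astype(np.float64), geom)


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
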