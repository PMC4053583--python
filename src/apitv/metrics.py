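"""Image-quality metrics and profile extraction.

The headline figure of merit is the plain sum of squared pixel
differences

    E = sum_i (f*_i - f_i)^2

between a reconstruction f and the true image f* — no square root and no
normalization.  A root-mean-square variant is provided under a distinct
name to avoid conflation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import ImageGrid

__all__ = ["image_error", "rmse", "extract_profile", "convergence_curve"]


def _data(img) -> np.ndarray:
    return np.asarray(img.data if isinstance(img, ImageGrid) else img, dtype=float)


def image_error(recon, truth) -> float:
    """Sum of squared pixel differences between reconstruction and truth."""
    a = _data(recon)
    b = _data(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.sum(d * d))


def rmse(recon, truth) -> float:
    """Root mean squared pixel difference (normalized variant of the
    sum-of-squares error)."""
    a = _data(recon)
    return float(np.sqrt(image_error(recon, truth) / a.size))


def extract_profile(img, row: int) -> np.ndarray:
    """Pixel values of one image row, left to right.

    ``row`` is 0-based; the conventional "128th row" of a 256-image is
    index 127.
    """
    data = _data(img)
    if not 0 <= row < data.shape[0]:
        raise IndexError(f"row {row} out of range [0, {data.shape[0]})")
    return data[row, :].copy()


def convergence_curve(result) -> pd.DataFrame:
    """Tabulate the per-main-iteration image error of a reconstruction run
    as a two-column table (iteration, error), 1-based iterations."""
    if result.error_history is None:
        raise ValueError(
            "result carries no error_history; rerun the reconstruction with "
            "the true image supplied (truth=...) to record per-iteration errors"
        )
    err = np.asarray(result.error_history, dtype=float)
    return pd.DataFrame(
        {"iteration": np.arange(1, err.size + 1), "error": err}
    )
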