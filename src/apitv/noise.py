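"""Additive white noise for sinograms.

"Percent white noise" is modeled as zero-mean Gaussian noise added to
every sinogram entry with standard deviation

    sigma = level * reference(sinogram),

where the reference amplitude defaults to the RMS of the nonzero
entries.  Alternative references (max, mean of absolute nonzero entries)
are available since percent-noise statements are ambiguous about the
normalization.  Photon-statistics (Poisson) noise is deliberately not
modeled; the corruption is purely additive.
"""

from __future__ import annotations

import numpy as np

from .projector import Sinogram

__all__ = ["add_white_noise", "noise_reference"]


def noise_reference(data: np.ndarray, reference: str = "rms") -> float:
    """Amplitude that 'percent noise' is taken relative to."""
    nz = np.abs(data[data != 0])
    if nz.size == 0:
        return 0.0
    if reference == "rms":
        return float(np.sqrt(np.mean(nz**2)))
    if reference == "max":
        return float(nz.max())
    if reference == "mean":
        return float(nz.mean())
    raise ValueError(f"unknown reference {reference!r}; valid: rms, max, mean")


def add_white_noise(
    sino: Sinogram,
    level: float,
    seed: int,
    reference: str = "rms",
) -> Sinogram:
    """Return ``sino + eta`` with eta ~ N(0, (level * ref)^2) i.i.d.

    Deterministic given ``seed``; the noise realization depends only on
    the seed, the sinogram shape and the scalar sigma, not on the
    individual entries.
    """
    if level < 0:
        raise ValueError("noise level must be nonnegative")
    if level == 0:
        return sino.copy()
    sigma = level * noise_reference(sino.data, reference)
    rng = np.random.default_rng(seed)
    # standard normal draws scaled afterwards: the noise *pattern* depends
    # only on seed and shape, the amplitude only on the scalar sigma
    eta = sigma * rng.standard_normal(sino.data.shape)
    return Sinogram(sino.data + eta, sino.geom)
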