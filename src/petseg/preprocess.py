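"""Slice enhancement ahead of segmentation: denoising and intensity scaling.

The network's tangent-sigmoid hidden layer needs bounded inputs, so volumes
are min-max normalised to [0, 1] per volume (not per slice, to keep slices
intensity-comparable).  Denoising is configurable; note that a 3x3 median
erases lesions smaller than about 3 voxels across, so pipelines aimed at
2-3-voxel tumours should use ``method="none"`` or a light Gaussian.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volume_io import PETVolume

__all__ = ["denoise", "normalize"]

log = logging.getLogger(__name__)

_METHODS = ("median", "gaussian", "none")


def denoise(volume: PETVolume, method: str = "median", size: int = 3) -> PETVolume:
    """Per-slice noise suppression.

    Parameters
    ----------
    method : {"median", "gaussian", "none"}
        ``median`` applies a size x size in-plane median filter; ``gaussian``
        an in-plane Gaussian of sigma ``size`` voxels (reflect boundary,
        intensity-conserving); ``none`` is the identity.
    size : int
        Filter window (median) or sigma in voxels (gaussian); >= 1.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown denoise method {method!r}; choose from {_METHODS}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if method == "none":
        return volume.with_voxels(volume.voxels.copy())
    if method == "median":
        out = ndimage.median_filter(volume.voxels, size=(size, size, 1), mode="reflect")
    else:
        out = ndimage.gaussian_filter(volume.voxels, sigma=(size, size, 0), mode="reflect")
    log.debug("denoise method=%s size=%d", method, size)
    return volume.with_voxels(np.clip(out, 0.0, None))


def normalize(volume: PETVolume) -> PETVolume:
    """Linear min-max rescale of the whole volume to [0, 1].

    A constant volume has no contrast to rescale; it maps to all zeros with
    a logged warning.  Idempotent, and preserves intensity ranking.
    """
    v = volume.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        log.warning("normalize: constant volume (value %g); output is all zeros", hi)
        return volume.with_voxels(np.zeros_like(v))
    return volume.with_voxels((v - lo) / (hi - lo))
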