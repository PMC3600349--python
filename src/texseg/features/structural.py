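"""Structural (macrotexture) features: morphological gradient and
left-right symmetry.

These operate on whole volumes rather than isolated windows: the
morphological gradient uses a spherical structuring element, and the
left-right symmetry ratio compares the volume with its mirror image
across the mid-sagittal plane (the last array axis).  The per-voxel
feature values are then windowed statistics of these auxiliary maps.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import ball


def morphological_gradient(data: np.ndarray, radius: int = 2) -> np.ndarray:
    """Grey-level dilation minus erosion with a ball of the given voxel radius."""
    footprint = ball(radius)
    data = np.asarray(data, dtype=np.float64)
    return ndimage.grey_dilation(data, footprint=footprint) - ndimage.grey_erosion(
        data, footprint=footprint
    )


def lr_symmetry_ratio(data: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """Voxel-wise ratio of the volume to its left-right mirror.

    The volume is shifted to be non-negative and both numerator and
    denominator are offset by ``eps`` (one intensity unit) so the ratio
    is defined in air.  A mirror-symmetric volume maps to 1 everywhere.
    """
    data = np.asarray(data, dtype=np.float64)
    lo = data.min()
    if lo < 0:
        data = data - lo
    mirrored = data[:, :, ::-1]
    return (data + eps) / (mirrored + eps)
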