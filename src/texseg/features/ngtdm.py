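"""Neighbourhood grey-tone difference matrix (NGTDM) texture features.

The NGTDM records, per occurring grey level, the summed absolute
deviation of voxels of that level from the mean of their 26-voxel
neighbourhood.  Coarseness, contrast ("N-contrast") and busyness are
derived from it following Amadasun and King, with every term normalized
by the mean grey level of the patch so the three features are invariant
to multiplicative intensity rescaling (with proportional binning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: Sentinel returned as coarseness of a perfectly uniform patch
#: (reciprocal of the epsilon guarding the coarseness denominator).
COARSENESS_MAX = 1e6
_EPS = 1.0 / COARSENESS_MAX

_KERNEL = np.ones((3, 3, 3))
_KERNEL[1, 1, 1] = 0.0  # 26 neighbours, centre excluded


@dataclass
class NGTDMatrix:
    """Per-level grey-tone difference sums over the valid interior of a patch."""

    levels: np.ndarray  # occurring grey levels among valid voxels
    s: np.ndarray  # summed |level - neighbourhood mean| per level
    p: np.ndarray  # occurrence probability per level (sums to 1)
    n_valid: int  # number of interior voxels considered
    mean_level: float  # mean grey level of the valid voxels

    def __post_init__(self) -> None:
        if np.any(self.s < -1e-12):
            raise ValueError("s entries must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("p must sum to 1 over occurring levels")


def ngtdm(patch: np.ndarray) -> NGTDMatrix:
    """Build the NGTDM of a quantized 3D patch.

    Only interior voxels whose full 3x3x3 neighbourhood lies inside the
    patch contribute, so the patch must exceed 3 voxels along two axes
    and reach 3 along the third.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3:
        raise ValueError("patch must be 3D")
    if any(n < 3 for n in patch.shape):
        raise ValueError("patch must contain a 3x3x3 interior neighbourhood")
    nb_sum = ndimage.convolve(patch, _KERNEL, mode="constant")
    interior = tuple(slice(1, n - 1) for n in patch.shape)
    vals = patch[interior].ravel()
    if vals.size == 0:
        raise ValueError("patch has no interior voxels")
    nb_mean = nb_sum[interior].ravel() / 26.0
    dev = np.abs(vals - nb_mean)
    levels, inv = np.unique(vals, return_inverse=True)
    s = np.zeros(levels.size)
    np.add.at(s, inv, dev)
    counts = np.bincount(inv, minlength=levels.size).astype(np.float64)
    p = counts / vals.size
    return NGTDMatrix(
        levels=levels, s=s, p=p, n_valid=int(vals.size), mean_level=float(vals.mean())
    )


def ngtdm_features(m: NGTDMatrix) -> dict[str, float]:
    """Coarseness, N-contrast and busyness from an NGTDM.

    A uniform patch (single occurring level, or all levels zero) yields
    the coarseness sentinel and zero contrast/busyness.
    """
    mu = m.mean_level
    n_levels = m.levels.size
    if n_levels < 2 or mu <= 0:
        return {"coarseness": COARSENESS_MAX, "n_contrast": 0.0, "busyness": 0.0}
    s_norm = m.s / mu

    psum = float(np.dot(m.p, s_norm))
    coarseness = min(1.0 / (_EPS + psum), COARSENESS_MAX)

    # pairwise terms over occurring levels
    li = m.levels[:, None]
    lj = m.levels[None, :]
    pi = m.p[:, None]
    pj = m.p[None, :]
    pair_contrast = float(np.sum(pi * pj * ((li - lj) / mu) ** 2))
    n_contrast = (
        pair_contrast / (n_levels * (n_levels - 1)) * (float(s_norm.sum()) / m.n_valid)
    )

    mobility = np.abs(li * pi - lj * pj) / mu
    denom = float(np.sum(mobility[~np.eye(n_levels, dtype=bool)]))
    busyness = psum / denom if denom > 0 else 0.0

    return {"coarseness": coarseness, "n_contrast": n_contrast, "busyness": busyness}
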