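"""Grey-level co-occurrence (SGLDM) matrices and second-order texture features.

The co-occurrence matrix records how often pairs of grey levels occur at
adjoining voxel positions.  Matrices are accumulated over a set of offsets
and symmetrized, so ``P`` is a joint relative-frequency matrix with
``P == P.T`` and ``P.sum() == 1``.

Only the grey levels that actually occur in a patch are represented
(the matrix rows carry their original level values), which bounds the
matrix size without altering any feature that depends on level
differences or sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: 13 unique 3D offsets covering all 26 adjoining-voxel directions after
#: symmetrization (Chebyshev distance 1).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: The four classical in-plane directions (0, 45, 90, 135 degrees).
OFFSETS_INPLANE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 1),
    (0, 1, 0),
    (0, 1, -1),
)

OFFSET_SETS = {"3d": OFFSETS_3D, "inplane": OFFSETS_INPLANE}


@dataclass
class CooccurrenceMatrix:
    """Symmetric joint relative-frequency matrix over occurring grey levels.

    ``levels[i]`` is the original grey level of row/column ``i`` and
    ``n_levels`` the total number of levels of the quantization rule
    (the period used by the consistency feature).
    """

    P: np.ndarray
    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")
        if self.P.shape[0] != self.levels.size:
            raise ValueError("level values must match matrix size")
        if np.any(self.P < 0):
            raise ValueError("P entries must be non-negative")
        total = self.P.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"P must sum to 1 (got {total})")
        if not np.allclose(self.P, self.P.T, atol=1e-12):
            raise ValueError("P must be symmetric")


def sgldm(
    patch: np.ndarray,
    offsets: Iterable[Sequence[int]] = OFFSETS_3D,
    n_levels: int | None = None,
) -> CooccurrenceMatrix:
    """Accumulate the co-occurrence matrix of a quantized patch.

    Pairs are counted in both directions for every offset (symmetrization)
    and the matrix is normalized to sum to 1.

    Parameters
    ----------
    patch : integer grey-level array (3D).
    offsets : voxel displacements ``(dz, dy, dx)`` at distance 1.
    n_levels : grey-level count of the quantization rule; defaults to
        ``patch.max() + 1``.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3:
        raise ValueError("patch must be 3D")
    levels = np.unique(patch)
    idx = np.searchsorted(levels, patch)
    k = levels.size
    counts = np.zeros((k, k), dtype=np.float64)
    n_pairs = 0
    for off in offsets:
        src = tuple(
            slice(None) if d == 0 else (slice(None, -d) if d > 0 else slice(-d, None))
            for d in off
        )
        dst = tuple(
            slice(None) if d == 0 else (slice(d, None) if d > 0 else slice(None, d))
            for d in off
        )
        a = idx[src].ravel()
        b = idx[dst].ravel()
        if a.size == 0:
            continue
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
        n_pairs += 2 * a.size
    if n_pairs == 0:
        raise ValueError("patch admits no voxel pairs for the given offsets")
    counts /= n_pairs
    if n_levels is None:
        n_levels = int(patch.max()) + 1
    return CooccurrenceMatrix(P=counts, levels=levels, n_levels=n_levels)


def consistency(C: CooccurrenceMatrix) -> float:
    """Occurrence-homogeneity measure in [-1, 1].

    Projects the co-occurrence mass onto a cosine of the level difference
    with period equal to the full grey-level range:
    ``sum_ij P(i,j) cos((i - j) * 2*pi / N_g)``.  All mass on the diagonal
    gives 1; mass at half-period differences gives -1.
    """
    ii, jj = np.nonzero(C.P)
    p = C.P[ii, jj]
    diff = C.levels[ii] - C.levels[jj]
    return float(np.sum(p * np.cos(diff * (2.0 * np.pi / C.n_levels))))


def haralick_features(C: CooccurrenceMatrix) -> dict[str, float]:
    """Classical second-order features of a co-occurrence matrix.

    Returns energy, entropy (bits), sum average, homogeneity, correlation,
    dissimilarity, contrast (``s_contrast``), cluster shade, and the
    consistency measure.  Correlation of a zero-variance marginal is 0.
    """
    ii, jj = np.nonzero(C.P)
    p = C.P[ii, jj]
    li = C.levels[ii]
    lj = C.levels[jj]
    diff = li - lj
    ssum = li + lj

    # marginal moments (P symmetric, so both marginals coincide)
    px = C.P.sum(axis=1)
    mu = float(np.dot(px, C.levels))
    var = float(np.dot(px, (C.levels - mu) ** 2))

    energy = float(np.sum(p * p))
    entropy = float(-np.sum(p * np.log2(p)))
    sum_average = float(np.sum(p * ssum))
    homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))
    dissimilarity = float(np.sum(p * np.abs(diff)))
    s_contrast = float(np.sum(p * diff**2))
    cluster_shade = float(np.sum(p * (ssum - 2.0 * mu) ** 3))
    if var > 0:
        correlation = float(np.sum(p * (li - mu) * (lj - mu)) / var)
    else:
        correlation = 0.0
    return {
        "energy": energy,
        "entropy": entropy,
        "sum_average": sum_average,
        "homogeneity": homogeneity,
        "correlation": correlation,
        "dissimilarity": dissimilarity,
        "s_contrast": s_contrast,
        "cluster_shade": cluster_shade,
        "consistency": consistency(C),
    }
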