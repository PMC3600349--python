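"""Tamura perceptual texture features: contrast and directionality.

Of the six Tamura attributes only contrast and directionality are
computed; both are well defined on a small anisotropic neighbourhood.
"""

from __future__ import annotations

import numpy as np


def tamura_contrast(values: np.ndarray) -> float:
    """Tamura contrast ``sigma / alpha4**(1/4)``.

    ``alpha4 = mu4 / sigma**4`` is the (non-excess) kurtosis, which
    measures the polarization of the grey-level distribution; a constant
    window has contrast 0.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("window is empty")
    d = v - v.mean()
    m2 = float(np.mean(d * d))
    if m2 <= 0:
        return 0.0
    m4 = float(np.mean(d**4))
    alpha4 = m4 / m2**2
    return float(np.sqrt(m2) / alpha4**0.25)


def tamura_directionality(window: np.ndarray) -> float:
    """Dominance of a single in-plane edge orientation, in [0, 1].

    In-plane (per-slice) intensity gradients are computed by central
    differences; each gradient contributes its orientation (modulo pi)
    weighted by its magnitude.  The result is the mean resultant length
    of the doubled-angle distribution: 1 when all gradients share one
    orientation, 0 for a window with no gradients (or an isotropic
    orientation spread).
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 3:
        raise ValueError("window must be 3D (slices, rows, columns)")
    if w.shape[1] < 2 or w.shape[2] < 2:
        return 0.0
    gy = np.gradient(w, axis=1)
    gx = np.gradient(w, axis=2)
    mag = np.hypot(gx, gy)
    total = float(mag.sum())
    if total <= 0:
        return 0.0
    theta2 = 2.0 * np.arctan2(gy, gx)
    c = float(np.sum(mag * np.cos(theta2))) / total
    s = float(np.sum(mag * np.sin(theta2))) / total
    return float(np.hypot(c, s))
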