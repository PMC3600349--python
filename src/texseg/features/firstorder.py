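"""First-order histogram statistics of a neighbourhood window."""

from __future__ import annotations

import numpy as np


def first_order(values: np.ndarray) -> dict[str, float]:
    """Mean, median, standard deviation, skewness and kurtosis of a window.

    The standard deviation uses the sample (n-1) convention; skewness and
    kurtosis are the population moment ratios, with kurtosis reported as
    excess kurtosis.  Zero-variance windows yield 0 for std, skewness and
    kurtosis.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("window is empty")
    mean = float(v.mean())
    median = float(np.median(v))
    d = v - mean
    m2 = float(np.mean(d * d))
    # guard against float round-off on constant windows
    if m2 <= (1e-12 * max(abs(mean), 1.0)) ** 2 or v.size < 2:
        return {"mean": mean, "median": median, "std": 0.0, "skewness": 0.0, "kurtosis": 0.0}
    std = float(np.sqrt(m2 * v.size / (v.size - 1)))
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    skewness = m3 / m2**1.5
    kurtosis = m4 / m2**2 - 3.0
    return {
        "mean": mean,
        "median": median,
        "std": std,
        "skewness": skewness,
        "kurtosis": kurtosis,
    }
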