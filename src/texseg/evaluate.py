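"""Consensus ground truth and segmentation metrics.

STAPLE (simultaneous truth and performance level estimation) combines
several binary observer masks into a per-voxel probability of the
abnormal class while jointly estimating each observer's sensitivity and
specificity by expectation-maximization.  Segmentations are then scored
against this probabilistic truth with probability-weighted sensitivity,
specificity and Dice; with a binary truth these reduce exactly to the
classical confusion-matrix formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class StapleResult:
    """Probabilistic truth plus per-rater performance estimates."""

    probabilities: np.ndarray  # per-voxel P(abnormal), in [0, 1]
    sensitivities: np.ndarray  # per rater
    specificities: np.ndarray
    prior: float
    n_iter: int
    converged: bool
    log_likelihood: list[float] | None = None  # per-iteration observed-data loglik


def staple(
    masks: Sequence[np.ndarray],
    tolerance: float = 1e-6,
    max_iter: int = 100,
) -> StapleResult:
    """EM estimation of a probabilistic truth from >= 2 binary masks.

    The E-step computes the per-voxel posterior of the abnormal class
    from the current rater performance estimates and a stationary global
    prior (the mean foreground fraction of the inputs); the M-step
    re-estimates each rater's sensitivity/specificity against that
    posterior.  Iteration stops when the maximum absolute posterior
    change drops below ``tolerance``.
    """
    if len(masks) < 2:
        raise ValueError("STAPLE needs at least two masks")
    D = np.stack([np.asarray(m, dtype=bool).ravel() for m in masks])
    shape = np.asarray(masks[0]).shape
    if any(np.asarray(m).shape != shape for m in masks):
        raise ValueError("masks must share one grid")
    if not D.any():
        raise ValueError("all masks are empty")
    R, N = D.shape
    prior = float(D.mean())
    sens = np.full(R, 0.99)
    spec = np.full(R, 0.99)
    W = np.full(N, prior)
    converged = False
    loglik: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        a = np.full(N, prior)
        b = np.full(N, 1.0 - prior)
        for r in range(R):
            d = D[r]
            a *= np.where(d, sens[r], 1.0 - sens[r])
            b *= np.where(d, 1.0 - spec[r], spec[r])
        loglik.append(float(np.sum(np.log(np.maximum(a + b, 1e-300)))))
        W_new = a / np.maximum(a + b, 1e-300)
        delta = float(np.max(np.abs(W_new - W)))
        W = W_new
        # M-step
        wsum = W.sum()
        csum = (1.0 - W).sum()
        for r in range(R):
            d = D[r]
            sens[r] = float(W[d].sum() / wsum) if wsum > 0 else 1.0
            spec[r] = float((1.0 - W)[~d].sum() / csum) if csum > 0 else 1.0
        if delta < tolerance:
            converged = True
            break
    return StapleResult(
        probabilities=W.reshape(shape),
        sensitivities=sens,
        specificities=spec,
        prior=prior,
        n_iter=it,
        converged=converged,
        log_likelihood=loglik,
    )


@dataclass
class EvalReport:
    """Probability-weighted segmentation metrics (nan = undefined)."""

    sensitivity: float
    specificity: float
    dice: float
    segment_voxels: int

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dice": self.dice,
            "segment_voxels": self.segment_voxels,
        }


def weighted_metrics(truth: np.ndarray, segment: np.ndarray) -> EvalReport:
    """Sensitivity, specificity and Dice weighted by a probabilistic truth.

    With truth probabilities ``P(T)`` and the segment mask splitting the
    domain into inside/outside sets,

    * sensitivity = (truth mass inside) / (total truth mass),
    * specificity = (complement mass outside) / (total complement mass),
    * Dice = 2 * (truth mass inside) / (total truth mass + segment volume).

    A binary truth reduces these to the classical confusion-matrix
    formulas.  Division-by-zero cases yield nan sentinels.
    """
    P = np.asarray(truth, dtype=np.float64)
    if isinstance(truth, StapleResult):  # convenience
        P = truth.probabilities
    seg = np.asarray(segment, dtype=bool)
    if P.shape != seg.shape:
        raise ValueError("truth and segment must share one grid")
    if P.min() < -1e-12 or P.max() > 1 + 1e-12:
        raise ValueError("truth probabilities must lie in [0, 1]")
    Pin = float(P[seg].sum())
    Pout = float(P[~seg].sum())
    Fin = float((1.0 - P)[seg].sum())
    Fout = float((1.0 - P)[~seg].sum())
    n_seg = int(seg.sum())
    sens = Pin / (Pin + Pout) if Pin + Pout > 0 else math.nan
    spec = Fout / (Fout + Fin) if Fout + Fin > 0 else math.nan
    denom = Pin + Pout + n_seg
    dice = 2.0 * Pin / denom if denom > 0 else math.nan
    return EvalReport(sensitivity=sens, specificity=spec, dice=dice, segment_voxels=n_seg)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Classical binary Dice overlap 2|A∩B| / (|A| + |B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float(np.count_nonzero(a & b)) / denom if denom else math.nan


def concordance_index(masks: Sequence[np.ndarray], variant: str = "pairwise") -> float:
    """Inter-observer concordance.

    ``pairwise`` (default): mean Jaccard index |A∩B| / |A∪B| over all
    unordered mask pairs.  ``all``: intersection of every mask over the
    union of every mask.
    """
    if len(masks) < 2:
        raise ValueError("concordance needs at least two masks")
    ms = [np.asarray(m, dtype=bool) for m in masks]
    if any(not m.any() for m in ms):
        raise ValueError("concordance is undefined for an empty mask")
    if variant == "all":
        inter = np.logical_and.reduce(ms)
        union = np.logical_or.reduce(ms)
        return float(inter.sum() / union.sum())
    if variant != "pairwise":
        raise ValueError(f"unknown variant {variant!r}")
    vals = []
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            inter = np.count_nonzero(ms[i] & ms[j])
            union = np.count_nonzero(ms[i] | ms[j])
            vals.append(inter / union)
    return float(np.mean(vals))


def variability_report(dice_values: Sequence[float]) -> float:
    """Sample standard deviation of Dice values as a percentage of their mean."""
    v = np.asarray(dice_values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("mean Dice is zero; relative variability undefined")
    return float(v.std(ddof=1) / mean * 100.0)
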