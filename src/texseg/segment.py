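"""Voxel-wise segmentation pipeline and baselines.

Stages, in fixed order: an intensity/busyness prefilter that restricts
classification to plausible soft-tissue voxels with tracer uptake; DTKNN
classification of the surviving candidates; removal of connected
components smaller than 0.5 cm^3; slice-wise morphological closing and
hole filling; and a final re-application of the CT window so the filled
mask cannot leak into bone or air.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .classify import DTKNNModel, KNNNode, Standardizer, dtknn_predict_batch, knn_predict, ABNORMAL
from .features.maps import FeatureExtractor
from .volumes import Volume

#: Fractional SUV-max levels offered by the percent-threshold baseline.
PERCENT_LEVELS = (0.20, 0.25, 0.30, 0.35, 0.40, 0.50)


@dataclass
class PrefilterRule:
    """Candidate-voxel gates: SUV floor, HU interval and PET-busyness band."""

    suv_floor: float = 1.0
    hu_window: tuple[float, float] = (-300.0, 200.0)
    busyness_max: float = 0.8
    exclude_zero_busyness: bool = True

    def __post_init__(self) -> None:
        if self.hu_window[1] <= self.hu_window[0]:
            raise ValueError("HU interval is empty")
        if self.suv_floor < 0:
            raise ValueError("SUV floor must be non-negative")

    def hu_gate(self, ct: np.ndarray) -> np.ndarray:
        lo, hi = self.hu_window
        return (ct >= lo) & (ct <= hi)


def intensity_gate(pet: Volume, ct: Volume, rule: PrefilterRule) -> np.ndarray:
    """SUV-floor and HU-window conjunction (no busyness yet)."""
    if pet.data.shape != ct.data.shape:
        raise ValueError("PET and CT must share the grid")
    return (pet.data > rule.suv_floor) & rule.hu_gate(ct.data)


def prefilter(
    pet: Volume, ct: Volume, busyness: np.ndarray, rule: PrefilterRule
) -> np.ndarray:
    """Candidate mask: uptake above the SUV floor, soft-tissue HU, and a
    PET busyness that is non-zero and below the cap."""
    gate = intensity_gate(pet, ct, rule)
    if busyness.shape != gate.shape:
        raise ValueError("busyness map shape mismatch")
    b = busyness < rule.busyness_max
    if rule.exclude_zero_busyness:
        b &= busyness != 0
    return gate & b


def classify_candidates(
    maps: Mapping[str, np.ndarray], candidates: np.ndarray, model: DTKNNModel
) -> np.ndarray:
    """DTKNN prediction inside the candidate mask; everything else is normal."""
    missing = [f for f in model.manifest if f not in maps]
    if missing:
        raise KeyError(f"feature maps missing for {missing}")
    out = np.zeros(candidates.shape, dtype=bool)
    voxels = np.argwhere(candidates)
    if len(voxels) == 0:
        return out
    X = pd.DataFrame({f: maps[f][tuple(voxels.T)] for f in model.manifest})
    out[tuple(voxels.T)] = dtknn_predict_batch(X, model)
    return out


def component_filter(
    mask: np.ndarray,
    spacing: Sequence[float],
    min_volume_cm3: float = 0.5,
    connectivity: int = 3,
) -> np.ndarray:
    """Drop connected components smaller than the volume floor.

    Components are 26-connected by default; the voxel volume is the
    product of the mm spacings divided by 1000.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    structure = ndimage.generate_binary_structure(3, connectivity)
    lab, n = ndimage.label(mask, structure=structure)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes * voxel_cm3 >= min_volume_cm3) + 1
    return np.isin(lab, keep)


def morph_postprocess(
    mask: np.ndarray, ct: Volume, rule: PrefilterRule, radius: int = 2
) -> np.ndarray:
    """Slice-wise disc dilation, closing, hole fill, erosion, then the CT window.

    The disc operations run in the transverse plane; interior cavities
    (e.g. necrotic cores missed by gradient-seeking features) are filled
    per slice, and the re-applied HU window removes any voxel that leaked
    into bone or air.
    """
    mask = np.asarray(mask, dtype=bool)
    d = disk(radius)[np.newaxis]  # slice-wise structuring element
    out = ndimage.binary_dilation(mask, structure=d)
    out = ndimage.binary_closing(out, structure=d)
    for z in range(out.shape[0]):
        out[z] = ndimage.binary_fill_holes(out[z])
    out = ndimage.binary_erosion(out, structure=d)
    return out & rule.hu_gate(ct.data)


# --------------------------------------------------------------------
# baselines


def threshold_baseline(
    pet: Volume, method: str = "absolute", value: float | None = None
) -> np.ndarray:
    """SUV-threshold segmentation baselines.

    ``method="absolute"`` keeps voxels with SUV >= value (default 2.5);
    ``method="percent"`` keeps voxels with SUV >= value * max(SUV)
    (value one of the classical fractions, default 0.30).
    """
    suv = pet.data
    if method == "absolute":
        thr = 2.5 if value is None else float(value)
        return suv >= thr
    if method == "percent":
        frac = 0.30 if value is None else float(value)
        if not 0 < frac < 1:
            raise ValueError("percent fraction must lie in (0, 1)")
        m = float(suv.max())
        if m <= 0:
            return np.zeros(suv.shape, dtype=bool)
        return suv >= frac * m
    raise ValueError(f"unknown threshold method {method!r}")


def husuv_knn_baseline(
    pet: Volume,
    ct: Volume,
    samples: tuple[pd.DataFrame, np.ndarray],
    candidates: np.ndarray,
    k: int = 7,
) -> np.ndarray:
    """Single-KNN baseline using only mean SUV and mean HU.

    ``samples`` is the (features, labels) pair of the ROI sample table;
    only the ``pet_mean`` / ``ct_mean`` columns are used.  Candidate
    voxels are classified by their window-mean intensities.
    """
    X, y = samples
    cols = ["ct_mean", "pet_mean"]
    std = Standardizer.fit(X[cols])
    Xs = std.transform(X[cols])
    node = KNNNode(
        features=tuple(std.features),
        X=Xs.to_numpy(np.float64),
        y=np.asarray(y, dtype=bool),
        sample_idx=np.arange(len(Xs)),
        k=k,
    )
    out = np.zeros(candidates.shape, dtype=bool)
    voxels = np.argwhere(candidates)
    if len(voxels) == 0:
        return out
    ex = FeatureExtractor(ct, pet)
    feats = ex.features_at(voxels, cols)
    Q = std.transform(pd.DataFrame(feats)).to_numpy(np.float64)
    preds = np.array(
        [knn_predict(q, node)[0] == ABNORMAL for q in Q], dtype=bool
    )
    out[tuple(voxels.T)] = preds
    return out


# --------------------------------------------------------------------
# pipeline


@dataclass
class SegmentationResult:
    mask: np.ndarray
    candidates: np.ndarray
    counts: dict[str, int] = field(default_factory=dict)
    busyness: np.ndarray | None = None


def segment_case(
    ct: Volume,
    pet_on_ct: Volume,
    model: DTKNNModel,
    rule: PrefilterRule | None = None,
    extractor: FeatureExtractor | None = None,
) -> SegmentationResult:
    """Run the full pipeline on a co-registered case (PET already on the CT grid)."""
    rule = rule or PrefilterRule()
    ex = extractor or FeatureExtractor(ct, pet_on_ct)
    gate = intensity_gate(pet_on_ct, ct, rule)
    busyness = ex.maps(["pet_busyness"], mask=gate)["pet_busyness"]
    cand = prefilter(pet_on_ct, ct, busyness, rule)
    maps = ex.maps(list(model.manifest), mask=cand)
    raw = classify_candidates(maps, cand, model)
    filtered = component_filter(raw, ct.spacing)
    final = morph_postprocess(filtered, ct, rule)
    counts = {
        "intensity_gate": int(gate.sum()),
        "candidates": int(cand.sum()),
        "classified": int(raw.sum()),
        "component_filtered": int(filtered.sum()),
        "final": int(final.sum()),
    }
    return SegmentationResult(mask=final, candidates=cand, counts=counts, busyness=busyness)
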