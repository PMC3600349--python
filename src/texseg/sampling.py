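"""ROI slice sampling: turn labelled regions into training samples.

Each ROI is shrunk by a physical margin (default 7 mm) so that sliding-
window features are not contaminated by the sharp intensity step at
organ boundaries, and the window features are averaged per axial slice:
one slice of one ROI yields one training sample.  To keep feature
computation tractable, at most ``max_voxels_per_slice`` evenly spaced
voxels of a slice contribute to the average.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .classify import ABNORMAL, NORMAL, TrainingSample
from .features.maps import FeatureExtractor, feature_names
from .volumes import erode_roi_margin


def _subsample(voxels: np.ndarray, cap: int) -> np.ndarray:
    if len(voxels) <= cap:
        return voxels
    pick = np.unique(np.linspace(0, len(voxels) - 1, cap).round().astype(int))
    return voxels[pick]


def roi_slice_samples(
    extractor: FeatureExtractor,
    labels: np.ndarray,
    label_names: Mapping[int, str],
    spacing: Sequence[float],
    patient_id: str = "",
    abnormal_tissues: Sequence[str] = ("tumor",),
    exclude_tissues: Sequence[str] = ("lung_left", "lung_right"),
    margin_mm: float = 7.0,
    min_voxels: int = 6,
    max_voxels_per_slice: int = 20,
    features: Sequence[str] | None = None,
) -> list[TrainingSample]:
    """Slice-averaged window features for every labelled ROI.

    Returns one sample per (ROI, axial slice) with at least
    ``min_voxels`` voxels remaining after margin erosion; the sample
    label is abnormal for tissues listed in ``abnormal_tissues``.
    """
    if features is None:
        features = feature_names()
    samples: list[TrainingSample] = []
    for lab, tissue in sorted(label_names.items()):
        if tissue in exclude_tissues:
            continue
        roi = erode_roi_margin(labels == lab, margin_mm, spacing)
        if not roi.any():
            continue
        label = ABNORMAL if tissue in abnormal_tissues else NORMAL
        for z in np.flatnonzero(roi.any(axis=(1, 2))):
            voxels = np.argwhere(roi[z])
            if len(voxels) < min_voxels:
                continue
            voxels = _subsample(voxels, max_voxels_per_slice)
            idx = np.column_stack([np.full(len(voxels), z), voxels])
            cols = extractor.features_at(idx, features)
            samples.append(
                TrainingSample(
                    features={n: float(np.mean(v)) for n, v in cols.items()},
                    label=label,
                    patient_id=patient_id,
                    slice_index=int(z),
                    tissue=tissue,
                )
            )
    return samples
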