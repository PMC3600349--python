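"""Sliding-window computation of the 43-feature PET/CT bank.

Every feature is evaluated over a neighbourhood window centred on each
voxel (default 3 slices x 7 rows x 7 columns, chosen so that the window
is roughly isotropic in millimetres at typical thoracic CT spacing).
Borders are handled by nearest-edge replication.  The bank comprises,
per modality:

* first order: mean, median, std, skewness, kurtosis
* second order (SGLDM): energy, entropy, sum average, homogeneity,
  correlation, dissimilarity, S-contrast, cluster shade, consistency
* higher order (NGTDM): coarseness, N-contrast, busyness
* structural: morphological gradient, its windowed std, left-right symmetry
* Tamura: contrast, and (CT only) directionality

giving 22 CT + 21 PET = 43 named features; directionality is omitted for
PET because its coarse in-plane resolution carries no reliable
orientation signal.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..volumes import QuantizationRule, Volume, ct_rule, pet_rule, quantize
from .cooccurrence import OFFSET_SETS, haralick_features, sgldm
from .firstorder import first_order
from .ngtdm import ngtdm, ngtdm_features
from .structural import lr_symmetry_ratio, morphological_gradient
from .tamura import tamura_contrast, tamura_directionality

DEFAULT_WINDOW: tuple[int, int, int] = (3, 7, 7)

FIRST_ORDER_NAMES = ("mean", "median", "std", "skewness", "kurtosis")
SGLDM_NAMES = (
    "energy",
    "entropy",
    "sum_average",
    "homogeneity",
    "correlation",
    "dissimilarity",
    "s_contrast",
    "cluster_shade",
    "consistency",
)
NGTDM_NAMES = ("coarseness", "n_contrast", "busyness")
STRUCTURAL_NAMES = ("morph_gradient", "morph_gradient_std", "lr_symmetry")
TAMURA_NAMES = ("t_contrast", "directionality")

_FAMILY_OF = {}
for _n in FIRST_ORDER_NAMES:
    _FAMILY_OF[_n] = "first"
for _n in SGLDM_NAMES:
    _FAMILY_OF[_n] = "sgldm"
for _n in NGTDM_NAMES:
    _FAMILY_OF[_n] = "ngtdm"
for _n in STRUCTURAL_NAMES:
    _FAMILY_OF[_n] = "structural"
for _n in TAMURA_NAMES:
    _FAMILY_OF[_n] = "tamura"


def feature_names() -> list[str]:
    """The canonical ordered 43-feature name list (22 CT + 21 PET)."""
    names = [f"ct_{n}" for n in FIRST_ORDER_NAMES + SGLDM_NAMES + NGTDM_NAMES + STRUCTURAL_NAMES + TAMURA_NAMES]
    names += [
        f"pet_{n}"
        for n in FIRST_ORDER_NAMES + SGLDM_NAMES + NGTDM_NAMES + STRUCTURAL_NAMES + ("t_contrast",)
    ]
    return names


def _pad(arr: np.ndarray, half: Sequence[int]) -> np.ndarray:
    return np.pad(arr, [(h, h) for h in half], mode="edge")


class _ModalityData:
    """Padded sliding-window views of one modality's raw / quantized /
    auxiliary grids."""

    def __init__(self, vol: Volume, rule: QuantizationRule, window: Sequence[int]):
        half = tuple(w // 2 for w in window)
        qv = quantize(vol, rule)
        self.n_levels = qv.n_levels
        self.raw_w = sliding_window_view(_pad(vol.data.astype(np.float64), half), window)
        self.quant_w = sliding_window_view(_pad(qv.data, half), window)
        grad = morphological_gradient(vol.data)
        self.grad = grad
        self.grad_w = sliding_window_view(_pad(grad, half), window)
        self.ratio_w = sliding_window_view(
            _pad(lr_symmetry_ratio(vol.data), half), window
        )


class FeatureExtractor:
    """Computes window features and feature maps for a co-registered
    PET/CT pair on the CT grid.

    Parameters
    ----------
    ct, pet : Volumes on the same grid (PET already resampled to CT).
    ct_quant, pet_quant : quantization rules (defaults: 256-bin CT window,
        0.05-SUV PET bins capped at 512 levels).
    window : neighbourhood shape ``(slices, rows, columns)``.
    offsets : ``"3d"`` (13 adjoining-voxel directions) or ``"inplane"``
        (the four classical 2D directions).
    """

    border = "edge"

    def __init__(
        self,
        ct: Volume,
        pet: Volume,
        ct_quant: QuantizationRule | None = None,
        pet_quant: QuantizationRule | None = None,
        window: Sequence[int] = DEFAULT_WINDOW,
        offsets: str = "3d",
    ):
        if ct.data.shape != pet.data.shape:
            raise ValueError("PET must be resampled to the CT grid first")
        if offsets not in OFFSET_SETS:
            raise ValueError(f"unknown offset set {offsets!r}")
        self.window = tuple(int(w) for w in window)
        self.offsets = OFFSET_SETS[offsets]
        self.shape = ct.data.shape
        self._mod = {
            "ct": _ModalityData(ct, ct_quant or ct_rule(), self.window),
            "pet": _ModalityData(pet, pet_quant or pet_rule(), self.window),
        }

    # -- single-voxel computation ------------------------------------

    def _voxel_features(
        self, z: int, y: int, x: int, wanted: Mapping[str, set]
    ) -> dict[str, float]:
        out: dict[str, float] = {}
        for mod, families in wanted.items():
            md = self._mod[mod]
            if "first" in families:
                fo = first_order(md.raw_w[z, y, x])
                for k in FIRST_ORDER_NAMES:
                    out[f"{mod}_{k}"] = fo[k]
            if "sgldm" in families:
                C = sgldm(md.quant_w[z, y, x], self.offsets, n_levels=md.n_levels)
                hf = haralick_features(C)
                for k in SGLDM_NAMES:
                    out[f"{mod}_{k}"] = hf[k]
            if "ngtdm" in families:
                nf = ngtdm_features(ngtdm(md.quant_w[z, y, x]))
                for k in NGTDM_NAMES:
                    out[f"{mod}_{k}"] = nf[k]
            if "structural" in families:
                out[f"{mod}_morph_gradient"] = float(md.grad[z, y, x])
                out[f"{mod}_morph_gradient_std"] = first_order(md.grad_w[z, y, x])["std"]
                out[f"{mod}_lr_symmetry"] = float(np.mean(md.ratio_w[z, y, x]))
            if "tamura" in families:
                out[f"{mod}_t_contrast"] = tamura_contrast(md.raw_w[z, y, x])
                if mod == "ct":
                    out["ct_directionality"] = tamura_directionality(md.raw_w[z, y, x])
        return out

    @staticmethod
    def _wanted(names: Iterable[str]) -> dict[str, set]:
        wanted: dict[str, set] = {}
        for name in names:
            mod, _, feat = name.partition("_")
            if mod not in ("ct", "pet") or feat not in _FAMILY_OF:
                raise KeyError(f"unknown feature name {name!r}")
            if mod == "pet" and feat == "directionality":
                raise KeyError("directionality is not defined for PET")
            wanted.setdefault(mod, set()).add(_FAMILY_OF[feat])
        return wanted

    def features_at(
        self, voxels: np.ndarray, names: Sequence[str] | None = None
    ) -> dict[str, np.ndarray]:
        """Feature values at a list of voxel indices ``(N, 3)``.

        Returns a dict mapping feature name to an ``(N,)`` array, in the
        requested (or canonical) name order.
        """
        if names is None:
            names = feature_names()
        names = list(names)
        voxels = np.atleast_2d(np.asarray(voxels, dtype=np.intp))
        wanted = self._wanted(names)
        cols = {n: np.empty(len(voxels)) for n in names}
        for i, (z, y, x) in enumerate(voxels):
            vals = self._voxel_features(int(z), int(y), int(x), wanted)
            for n in names:
                cols[n][i] = vals[n]
        return cols

    def maps(
        self, names: Sequence[str] | None = None, mask: np.ndarray | None = None
    ) -> dict[str, np.ndarray]:
        """Per-voxel feature maps aligned to the CT grid.

        With a mask, features are evaluated only at mask voxels (0.0
        elsewhere) — segmentation only ever needs maps inside the
        candidate region.
        """
        if names is None:
            names = feature_names()
        if mask is None:
            voxels = np.argwhere(np.ones(self.shape, dtype=bool))
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.shape:
                raise ValueError("mask shape mismatch")
            voxels = np.argwhere(mask)
        cols = self.features_at(voxels, names)
        out = {}
        for n in names:
            m = np.zeros(self.shape, dtype=np.float64)
            m[tuple(voxels.T)] = cols[n]
            out[n] = m
        return out


def feature_maps(
    ct: Volume,
    pet: Volume,
    names: Sequence[str] | None = None,
    mask: np.ndarray | None = None,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Convenience wrapper: build an extractor and return feature maps."""
    return FeatureExtractor(ct, pet, **kwargs).maps(names, mask)
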