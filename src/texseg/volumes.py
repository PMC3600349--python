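"""Volumes, I/O, resampling, quantization, ROI margins, and SNR quality control.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` (slice, row, column); ``spacing`` and
``origin`` are millimetre tuples aligned with the *array* axes, i.e.
``spacing[0]`` is the slice thickness.  The left-right (sagittal mirror)
axis is the last array axis.  Masks are boolean arrays on the same grid
as the volume they refer to.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import SimpleITK as sitk

CT_HU = "CT-HU"
PET_SUV = "PET-SUV"


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry and a modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume grid must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_cm3(self) -> float:
        """Physical volume of one voxel in cm^3 (product of mm spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def physical_extent(self) -> list[tuple[float, float]]:
        """(low, high) physical coordinate per axis, voxel-centre convention."""
        return [
            (o, o + (n - 1) * s)
            for o, s, n in zip(self.origin, self.spacing, self.data.shape)
        ]

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.data)
        img.SetSpacing(tuple(reversed(self.spacing)))
        img.SetOrigin(tuple(reversed(self.origin)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: str | None = None) -> "Volume":
        return cls(
            data=sitk.GetArrayFromImage(img),
            spacing=tuple(reversed(img.GetSpacing())),
            origin=tuple(reversed(img.GetOrigin())),
            modality=modality,
        )


@dataclass
class QuantizationRule:
    """Maps continuous intensities to integer grey levels in [0, n_levels-1]."""

    kind: str  # "ct-window" | "pet-binwidth"
    n_levels: int
    window: tuple[float, float] | None = None  # ct-window
    bin_width: float | None = None  # pet-binwidth

    def describe(self) -> dict:
        return {
            "kind": self.kind,
            "n_levels": self.n_levels,
            "window": self.window,
            "bin_width": self.bin_width,
        }


def ct_rule(window: tuple[float, float] = (-1000.0, 1000.0), n_bins: int = 256) -> QuantizationRule:
    """CT rule: clip to a HU window, then uniform binning into ``n_bins`` levels.

    The window default covers lung through bone; it is configurable because
    the binning only fixes the number of levels, not the range.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("degenerate window: max must exceed min")
    return QuantizationRule(kind="ct-window", n_levels=int(n_bins), window=(float(lo), float(hi)))


def pet_rule(bin_width: float = 0.05, max_levels: int = 512) -> QuantizationRule:
    """PET rule: fixed SUV bin width (level = floor(SUV / width)), capped level count.

    The default cap of 512 levels (25.6 SUV at 0.05-wide bins) bounds the
    co-occurrence matrix size.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    return QuantizationRule(kind="pet-binwidth", n_levels=int(max_levels), bin_width=float(bin_width))


@dataclass
class QuantizedVolume:
    """Integer grey-level grid in [0, n_levels-1] plus the rule that produced it."""

    data: np.ndarray
    n_levels: int
    rule: QuantizationRule
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str | None = None

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 grey levels")


def quantize(vol: Volume, rule: QuantizationRule) -> QuantizedVolume:
    """Discretize a volume's intensities into integer grey levels."""
    v = np.asarray(vol.data, dtype=np.float64)
    if rule.kind == "ct-window":
        lo, hi = rule.window
        clipped = np.clip(v, lo, hi)
        levels = np.floor((clipped - lo) / (hi - lo) * rule.n_levels).astype(np.int32)
        np.clip(levels, 0, rule.n_levels - 1, out=levels)
    elif rule.kind == "pet-binwidth":
        levels = np.floor(np.maximum(v, 0.0) / rule.bin_width).astype(np.int32)
        np.clip(levels, 0, rule.n_levels - 1, out=levels)
    else:
        raise ValueError(f"unknown quantization rule kind {rule.kind!r}")
    return QuantizedVolume(
        data=levels,
        n_levels=rule.n_levels,
        rule=rule,
        spacing=vol.spacing,
        origin=vol.origin,
        modality=vol.modality,
    )


@dataclass
class SNRReport:
    """Signal-to-noise ratio of a region, defined as ROI mean over ROI std."""

    mean: float
    std: float
    snr: float
    modality: str | None = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.snr)


def compute_snr(vol: Volume, roi: np.ndarray) -> SNRReport:
    """SNR = mu / sigma over an ROI (sample std).  sigma = 0 yields an
    infinite sentinel rather than an exception."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vol.data.shape:
        raise ValueError("ROI grid does not match volume grid")
    vals = vol.data[roi]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    if sigma <= 1e-12 * max(abs(mu), 1.0):  # zero variance up to round-off
        sigma = 0.0
    snr = mu / sigma if sigma > 0 else math.inf
    return SNRReport(mean=mu, std=sigma, snr=snr, modality=vol.modality)


def load_volume(path, modality: str | None = None) -> Volume:
    """Read a NIfTI / MetaImage / NRRD volume."""
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot read volume from {path}: {exc}") from exc
    return Volume.from_sitk(img, modality=modality)


def save_volume(vol: Volume, path) -> None:
    """Write a volume; the format follows the file extension."""
    sitk.WriteImage(vol.to_sitk(), str(path))


def load_mask(path) -> np.ndarray:
    """Read a binary mask as a boolean array (any nonzero voxel is foreground)."""
    return load_volume(path).data > 0


def save_mask(mask: np.ndarray, spacing, path, origin=(0.0, 0.0, 0.0)) -> None:
    save_volume(Volume(np.asarray(mask, dtype=np.uint8), spacing, origin), path)


def resample_pet_to_ct(pet: Volume, ct: Volume) -> Volume:
    """Resample PET onto the CT grid by trilinear interpolation.

    Values outside the PET physical extent are filled with 0.  Raises if
    the physical extents of the two volumes do not overlap at all.
    """
    for (plo, phi), (clo, chi) in zip(pet.physical_extent(), ct.physical_extent()):
        if phi < clo or chi < plo:
            raise ValueError("PET and CT physical extents do not overlap")
    out = sitk.Resample(
        pet.to_sitk(),
        ct.to_sitk(),
        sitk.Transform(),
        sitk.sitkLinear,
        0.0,
        sitk.sitkFloat64,
    )
    res = Volume.from_sitk(out, modality=pet.modality)
    return res


def _ellipsoid_structure(radii_vox: Sequence[float]) -> np.ndarray:
    """Boolean ellipsoid footprint with the given per-axis radii in voxels."""
    half = [int(math.floor(r)) for r in radii_vox]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) for h in half], indexing="ij"
    )
    d2 = sum(
        (g / max(r, 1e-12)) ** 2 for g, r in zip(grids, radii_vox)
    )
    return d2 <= 1.0 + 1e-9


def erode_roi_margin(roi: np.ndarray, margin_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Shrink an ROI by a physical margin (ellipsoidal erosion in voxel units).

    A 7 mm margin is the usual choice to keep sliding-window texture
    measurements away from sharp organ boundaries.
    """
    from scipy import ndimage

    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    roi = np.asarray(roi, dtype=bool)
    if margin_mm == 0:
        return roi.copy()
    radii = [margin_mm / s for s in spacing]
    if all(r < 1 for r in radii):
        return roi.copy()
    structure = _ellipsoid_structure(radii)
    out = ndimage.binary_erosion(roi, structure=structure, border_value=0)
    if roi.any() and not out.any():
        warnings.warn("margin erosion emptied the ROI", stacklevel=2)
    return out
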