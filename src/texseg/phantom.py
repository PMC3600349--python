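"""Synthetic thoracic PET/CT phantoms with textured tumors and simulated raters.

The phantom is a miniature thorax: ellipsoidal organs (liver, heart,
spleen, muscle, ...) painted on a fine CT grid in Hounsfield units and on
a coarse native PET grid in SUV, a tumor whose interior uptake is a
two-level (thresholded) Gaussian random field at a controllable
correlation length, partial-volume blur on the PET, and additive noise
calibrated so the liver signal-to-noise ratio (ROI mean over ROI std)
hits a stated target.  Multi-observer contours are simulated by
spatially correlated label flips at chosen sensitivity/specificity.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import CT_HU, PET_SUV, Volume, compute_snr, erode_roi_margin

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class OrganSpec:
    """An ellipsoidal organ: geometry in mm plus mean intensities and texture."""

    name: str
    center_mm: tuple[float, float, float]  # (z, y, x)
    radii_mm: tuple[float, float, float]
    mean_hu: float
    mean_suv: float
    hu_texture: float = 0.0  # Gaussian-field amplitude (HU)
    suv_texture: float = 0.0  # Gaussian-field amplitude (SUV)
    texture_corr_mm: float = 4.0


@dataclass
class TumorSpec:
    """A heterogeneous tumor: uptake/attenuation alternate between the
    range bounds on blobs of the stated correlation length."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    suv_range: tuple[float, float] = (4.0, 9.0)
    hu_range: tuple[float, float] = (20.0, 60.0)
    corr_mm: float = 4.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]  # CT grid (slices, rows, cols)
    ct_spacing: tuple[float, float, float] = (2.5, 0.98, 0.98)
    pet_spacing: tuple[float, float, float] = (3.27, 3.9, 3.9)
    organs: list[OrganSpec] = field(default_factory=list)
    tumor: TumorSpec | None = None
    pet_fwhm_mm: float = 7.0
    ct_snr: float = 3.7
    pet_snr: float = 7.56
    noise_scale: float = 1.0  # multiplies the calibrated noise amplitude
    background_hu: float = -780.0
    background_suv: float = 0.35
    n_observers: int = 3
    observer_sens: float = 0.9
    observer_spec: float = 0.995
    #: inter-case variability: per-case lognormal sigma on mean SUV and
    #: additive HU standard deviation, mimicking interpatient and
    #: interscanner intensity variation
    suv_jitter: float = 0.10
    hu_jitter: float = 5.0
    #: slow within-case intensity drift (CT bias field in HU, PET
    #: multiplicative uptake gradient) at the stated correlation length
    ct_drift_hu: float = 6.0
    pet_drift_frac: float = 0.10
    drift_corr_mm: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.ct_spacing + self.pet_spacing):
            raise ValueError("spacings must be positive")
        if self.ct_snr <= 0 or self.pet_snr <= 0:
            raise ValueError("SNR targets must be positive")
        for o in self.organs:
            if any(r <= 0 for r in o.radii_mm):
                raise ValueError(f"organ {o.name!r} has non-positive radius")
        if self.tumor is not None and any(r <= 0 for r in self.tumor.radii_mm):
            raise ValueError("tumor has non-positive radius")
        if not any(o.name == "liver" for o in self.organs):
            raise ValueError("phantom requires a 'liver' organ for SNR calibration")


@dataclass
class PhantomOutput:
    ct: Volume
    pet: Volume  # native PET grid
    tumor_mask: np.ndarray  # CT grid
    labels: np.ndarray  # CT grid organ label map (0 = background)
    label_names: dict[int, str]
    observers: list[np.ndarray]
    spec: PhantomSpec

    def organ_mask(self, name: str) -> np.ndarray:
        for lab, n in self.label_names.items():
            if n == name:
                return self.labels == lab
        raise KeyError(name)

    def liver_roi(self, margin_mm: float = 7.0) -> np.ndarray:
        """Margin-eroded liver label, the ROI used for SNR quality control."""
        return erode_roi_margin(self.organ_mask("liver"), margin_mm, self.ct.spacing)


# --------------------------------------------------------------------


def gaussian_random_field(
    rng: np.random.Generator,
    shape: Sequence[int],
    corr_mm: float,
    spacing: Sequence[float],
) -> np.ndarray:
    """Zero-mean, unit-std Gaussian field with the given correlation length."""
    noise = rng.standard_normal(tuple(shape))
    sigma = [max(corr_mm / s, 1e-6) for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def _grid_coords(shape, spacing):
    return np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij", sparse=True
    )


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    zz, yy, xx = _grid_coords(shape, spacing)
    d2 = (
        ((zz - center_mm[0]) / radii_mm[0]) ** 2
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2
        + ((xx - center_mm[2]) / radii_mm[2]) ** 2
    )
    return d2 <= 1.0


def _paint(
    rng: np.random.Generator,
    shape,
    spacing,
    spec: PhantomSpec,
    intensity: str,  # "hu" | "suv"
) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Paint organs and tumor on one grid; returns (image, labels, names)."""
    img = np.full(
        shape, spec.background_hu if intensity == "hu" else spec.background_suv
    )
    labels = np.zeros(shape, dtype=np.int16)
    names: dict[int, str] = {}
    for i, organ in enumerate(spec.organs, start=1):
        mask = _ellipsoid_mask(shape, spacing, organ.center_mm, organ.radii_mm)
        mean = organ.mean_hu if intensity == "hu" else organ.mean_suv
        amp = organ.hu_texture if intensity == "hu" else organ.suv_texture
        vals = np.full(shape, mean)
        if amp > 0:
            vals = vals + amp * gaussian_random_field(
                rng, shape, organ.texture_corr_mm, spacing
            )
        img[mask] = vals[mask]
        labels[mask] = i
        names[i] = organ.name
    if spec.tumor is not None:
        t = spec.tumor
        mask = _ellipsoid_mask(shape, spacing, t.center_mm, t.radii_mm)
        lo, hi = t.suv_range if intensity == "suv" else t.hu_range
        blobs = gaussian_random_field(rng, shape, t.corr_mm, spacing) > 0
        vals = np.where(blobs, hi, lo)
        img[mask] = vals[mask]
        lab = len(spec.organs) + 1
        labels[mask] = lab
        names[lab] = "tumor"
    return img, labels, names


def _calibrate_noise(
    rng: np.random.Generator,
    img: np.ndarray,
    roi: np.ndarray,
    target_snr: float,
    scale: float,
) -> np.ndarray:
    """Add white noise so the ROI mean/std ratio matches the target SNR."""
    vals = img[roi]
    mu = vals.mean()
    var_present = vals.var(ddof=1) if vals.size > 1 else 0.0
    var_target = (mu / target_snr) ** 2
    if var_target <= var_present:
        if scale > 0:
            warnings.warn(
                "intrinsic ROI variance already exceeds the SNR target; "
                "no noise added",
                stacklevel=2,
            )
        return img
    sigma = np.sqrt(var_target - var_present) * scale
    if sigma <= 0:
        return img
    noise = rng.standard_normal(img.shape)
    # pin the realized noise moments inside the ROI so the measured SNR
    # matches the target rather than fluctuating with the draw
    noise -= noise[roi].mean()
    sd = noise[roi].std(ddof=1)
    if sd > 0:
        noise *= sigma / sd
    return img + noise


def _jitter_case(rng: np.random.Generator, spec: PhantomSpec) -> PhantomSpec:
    """Draw the case-level intensity offsets (interpatient variability).

    Each organ's mean SUV is scaled by a lognormal factor and its mean HU
    shifted by a Gaussian offset; the tumor's SUV/HU ranges move with the
    same kind of draw.  Zero jitter leaves the spec untouched."""
    if spec.suv_jitter <= 0 and spec.hu_jitter <= 0:
        return spec
    organs = []
    for o in spec.organs:
        f = float(np.exp(rng.normal(0.0, spec.suv_jitter)))
        dh = float(rng.normal(0.0, spec.hu_jitter))
        organs.append(replace(o, mean_suv=o.mean_suv * f, mean_hu=o.mean_hu + dh))
    tumor = spec.tumor
    if tumor is not None:
        f = float(np.exp(rng.normal(0.0, spec.suv_jitter)))
        dh = float(rng.normal(0.0, spec.hu_jitter))
        tumor = replace(
            tumor,
            suv_range=(tumor.suv_range[0] * f, tumor.suv_range[1] * f),
            hu_range=(tumor.hu_range[0] + dh, tumor.hu_range[1] + dh),
        )
    return replace(spec, organs=organs, tumor=tumor)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate one co-registered synthetic PET/CT case.

    The CT is painted at CT spacing; the PET is painted independently at
    its native coarse spacing, blurred by the scanner FWHM, then noise is
    added to each modality so the margin-eroded liver ROI reaches the
    spec's SNR targets (within sampling error).  Observer contours are
    drawn from the true tumor mask on the CT grid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spec = _jitter_case(rng, spec)

    # CT on its own grid
    ct_img, labels, names = _paint(rng, spec.shape, spec.ct_spacing, spec, "hu")
    if spec.ct_drift_hu > 0:
        soft = labels > 0
        drift = gaussian_random_field(rng, spec.shape, spec.drift_corr_mm, spec.ct_spacing)
        ct_img[soft] += spec.ct_drift_hu * drift[soft]
    tumor_mask = labels == (len(spec.organs) + 1)
    liver_lab = next(l for l, n in names.items() if n == "liver")
    liver_roi = erode_roi_margin(labels == liver_lab, 7.0, spec.ct_spacing)
    if not liver_roi.any():
        liver_roi = labels == liver_lab
    ct_img = _calibrate_noise(rng, ct_img, liver_roi, spec.ct_snr, spec.noise_scale)

    # PET on its native grid covering the same physical extent
    extent = [n * s for n, s in zip(spec.shape, spec.ct_spacing)]
    pet_shape = tuple(int(np.ceil(e / s)) for e, s in zip(extent, spec.pet_spacing))
    pet_img, _, _ = _paint(rng, pet_shape, spec.pet_spacing, spec, "suv")
    if spec.pet_drift_frac > 0:
        drift = gaussian_random_field(rng, pet_shape, spec.drift_corr_mm, spec.pet_spacing)
        pet_img *= 1.0 + spec.pet_drift_frac * drift
    sigma = [spec.pet_fwhm_mm / _FWHM_TO_SIGMA / s for s in spec.pet_spacing]
    pet_img = ndimage.gaussian_filter(pet_img, sigma=sigma, mode="nearest")
    pet_liver = _ellipsoid_mask(
        pet_shape,
        spec.pet_spacing,
        spec.organs[liver_lab - 1].center_mm,
        spec.organs[liver_lab - 1].radii_mm,
    )
    pet_liver_roi = erode_roi_margin(pet_liver, 7.0, spec.pet_spacing)
    if not pet_liver_roi.any():
        pet_liver_roi = pet_liver
    pet_img = _calibrate_noise(rng, pet_img, pet_liver_roi, spec.pet_snr, spec.noise_scale)
    np.clip(pet_img, 0.0, None, out=pet_img)

    observers = []
    if tumor_mask.any() and spec.n_observers > 0:
        observers = simulate_observers(
            tumor_mask,
            spec.n_observers,
            spec.observer_sens,
            spec.observer_spec,
            seed=int(rng.integers(2**31)),
        )

    return PhantomOutput(
        ct=Volume(ct_img, spec.ct_spacing, modality=CT_HU),
        pet=Volume(pet_img, spec.pet_spacing, modality=PET_SUV),
        tumor_mask=tumor_mask,
        labels=labels,
        label_names=names,
        observers=observers,
        spec=spec,
    )


def measured_snr(out: PhantomOutput, modality: str = "ct") -> float:
    """Liver-ROI SNR of a generated phantom (the quantity the calibration targets)."""
    if modality == "ct":
        return compute_snr(out.ct, out.liver_roi()).snr
    liver = out.organ_mask("liver")
    # transfer the liver geometry to the PET grid
    o = next(org for org in out.spec.organs if org.name == "liver")
    mask = _ellipsoid_mask(out.pet.shape, out.pet.spacing, o.center_mm, o.radii_mm)
    roi = erode_roi_margin(mask, 7.0, out.pet.spacing)
    if not roi.any():
        roi = mask
    return compute_snr(out.pet, roi).snr


# --------------------------------------------------------------------
# observers


def simulate_observers(
    true_mask: np.ndarray,
    n_raters: int,
    sens: float,
    spec_: float,
    seed: int = 0,
    smooth: bool = True,
    blob_sigma: float = 2.0,
) -> list[np.ndarray]:
    """Simulate rater contours at given per-rater sensitivity/specificity.

    Flip sites are the top quantiles of a smooth Gaussian random field,
    so rater errors form spatially plausible blobs rather than speckle.
    A 27-neighbourhood majority filter tidies the blob boundaries; since
    that trims some flips, the pre-filter flip counts are adjusted
    iteratively until the post-filter error rates match ``1 - sens``
    inside and ``1 - spec_`` outside the truth.
    """
    true_mask = np.asarray(true_mask, dtype=bool)
    if not true_mask.any():
        raise ValueError("true mask is empty")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    for p, nm in ((sens, "sens"), (spec_, "spec_")):
        if not 0.5 < p <= 1.0:
            raise ValueError(f"{nm} must lie in (0.5, 1]")

    masks = []
    inside = np.flatnonzero(true_mask.ravel())
    outside = np.flatnonzero(~true_mask.ravel())
    order_cache: dict[str, np.ndarray] = {}
    target_in = int(round((1.0 - sens) * inside.size))
    target_out = int(round((1.0 - spec_) * outside.size))
    for r in range(n_raters):
        rng = np.random.default_rng([seed, r])
        if target_in == 0 and target_out == 0:
            masks.append(true_mask.copy())
            continue
        f = ndimage.gaussian_filter(
            rng.standard_normal(true_mask.shape), sigma=blob_sigma
        ).ravel()
        in_sorted = inside[np.argsort(f[inside], kind="stable")]
        out_sorted = outside[np.argsort(f[outside], kind="stable")]

        def realize(n_in: int, n_out: int) -> np.ndarray:
            flips = np.zeros(true_mask.size, dtype=bool)
            if n_in > 0:
                flips[in_sorted[-n_in:]] = True
            if n_out > 0:
                flips[out_sorted[-n_out:]] = True
            flips = flips.reshape(true_mask.shape)
            if smooth:
                flips = ndimage.median_filter(flips.astype(np.uint8), size=3).astype(bool)
            return flips

        n_in, n_out = target_in, target_out
        flips = realize(n_in, n_out)
        if smooth:
            for _ in range(8):
                got_in = int(np.count_nonzero(flips[true_mask]))
                got_out = int(np.count_nonzero(flips[~true_mask]))
                if abs(got_in - target_in) <= max(1, target_in // 100) and abs(
                    got_out - target_out
                ) <= max(1, target_out // 100):
                    break
                n_in = int(np.clip(n_in + (target_in - got_in), 0, inside.size))
                n_out = int(np.clip(n_out + (target_out - got_out), 0, outside.size))
                flips = realize(n_in, n_out)
        masks.append(true_mask ^ flips)
    return masks


# --------------------------------------------------------------------
# ready-made study phantoms


def default_phantom_spec(seed: int = 0, shape=(28, 80, 96)) -> PhantomSpec:
    """A miniature thorax: a soft-tissue body holding two air-filled
    lungs, liver, heart, spleen and trapezius muscle, plus a bright
    heterogeneous tumor inside the right lung.

    Organs are embedded in soft tissue (as in a real thorax) so that
    only lung interfaces present the sharp air/tissue intensity step;
    the tumor sits in aerated lung like a typical carcinoma.  Painting
    order matters: later entries overwrite earlier ones.
    """
    return PhantomSpec(
        shape=shape,
        organs=[
            OrganSpec("body", (35.0, 39.0, 47.0), (70.0, 37.0, 46.0), 20.0, 0.7, 4.0, 0.05),
            OrganSpec("lung_right", (30.0, 36.0, 26.0), (26.0, 22.0, 17.0), -780.0, 0.25, 15.0, 0.02),
            OrganSpec("lung_left", (30.0, 36.0, 68.0), (26.0, 22.0, 17.0), -780.0, 0.25, 15.0, 0.02),
            OrganSpec("heart", (20.0, 42.0, 52.0), (14.0, 15.0, 15.0), 45.0, 2.0, 2.0, 0.08),
            OrganSpec("liver", (55.0, 44.0, 36.0), (17.0, 21.0, 23.0), 60.0, 2.2, 2.0, 0.08),
            OrganSpec("spleen", (55.0, 46.0, 73.0), (11.0, 10.0, 10.0), 50.0, 1.6, 2.0, 0.05),
            OrganSpec("muscle", (12.0, 12.0, 47.0), (15.0, 9.0, 28.0), 40.0, 0.8, 2.0, 0.04),
        ],
        tumor=TumorSpec((24.0, 32.0, 22.0), (13.0, 15.0, 15.0)),
        seed=seed,
    )


def easy_phantom_spec(seed: int = 0, shape=(28, 80, 96)) -> PhantomSpec:
    """High-contrast textured tumor at moderate noise (liver CT SNR 6,
    PET SNR at the typical scanner value)."""
    s = default_phantom_spec(seed=seed, shape=shape)
    return replace(s, ct_snr=6.0, pet_snr=7.56)


def overlapping_phantom_spec(seed: int = 0, shape=(28, 80, 96)) -> PhantomSpec:
    """Tumor whose mean SUV and HU overlap the liver/heart intensity range
    but whose interior is strongly textured — intensity alone cannot
    separate it, texture can."""
    s = default_phantom_spec(seed=seed, shape=shape)
    tumor = TumorSpec(
        s.tumor.center_mm,
        s.tumor.radii_mm,
        suv_range=(1.2, 3.2),  # brackets liver (2.2) and heart (2.0)
        hu_range=(30.0, 70.0),  # brackets liver (60) / spleen (50)
        corr_mm=6.0,  # coarse heterogeneity: the texture signature that
        # survives PET partial-volume blur
    )
    return replace(s, tumor=tumor, ct_snr=8.0, pet_snr=10.0)
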