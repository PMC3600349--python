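# texseg

Automatic lung-tumor segmentation in co-registered PET/CT using 3D
texture features and a decision tree of k-nearest-neighbour classifiers
(DTKNN), with synthetic phantoms for end-to-end validation.

## The problem

Delineating the gross tumor volume (GTV) is the largest source of
geometric uncertainty in thoracic radiotherapy: CT offers little
soft-tissue contrast around a tumor, and PET is blurry, coarse and only
semi-quantitative (SUV).  Fixed SUV thresholds cannot cope with
heterogeneous uptake, partial-volume effects or inflamed tissue.  This
package classifies each voxel as tumor or normal tissue from the joint
*texture* of the two modalities, which separates tissues whose raw
intensities overlap.

It is aimed at medical-physics and image-analysis researchers who want a
self-contained, testable implementation of texture-driven voxel
classification: no patient data are required, because a phantom module
generates paired PET/CT volumes with organ-like structure, textured
tumors, calibrated noise and simulated observer contours.

## The method

**Feature bank.** Every voxel is described by 43 features computed over
a 7×7×3 neighbourhood (approximately isotropic in mm at thoracic CT
spacing), 22 from CT and 21 from PET: first-order statistics (mean,
median, σ, skewness, kurtosis), second-order co-occurrence features over
all 13 adjoining-voxel directions (energy, entropy, sum average,
homogeneity, correlation, dissimilarity, contrast, cluster shade, and a
*consistency* measure

&nbsp;&nbsp;&nbsp;&nbsp;consistency = Σᵢⱼ P(i,j)·cos[(i−j)·2π/N_g],

which is 1 when all co-occurrence mass is diagonal and falls as grey
levels mix), grey-tone-difference features (coarseness, N-contrast,
busyness, normalized to be invariant to intensity rescaling),
structural features (morphological gradient with a radius-2 ball, its
windowed σ, left–right symmetry ratio), and Tamura contrast and (CT
only) directionality.  CT is quantized into 256 bins over a configurable
HU window; PET into fixed 0.05-SUV bins.

**Classifier.** A binary tree whose nodes are KNN classifiers (k = 7)
over at most three features.  Each node's subset is found by exhaustive
search maximizing AUC90 — the area under the leave-one-out ROC
restricted to specificity > 0.9 (maximum 0.1) — where the ROC is traced
by the vote fraction n_a/k.  The Euclidean distance is computed on
standardized features, Dᵢ = √Σⱼ(χⱼ − xⱼᵢ)², and the decision confidence
is max(n_a, n_n)/k.  Samples routed into the abnormal / normal branches
grow child nodes only while both classes keep ≥ 4 samples and whole-tree
leave-one-out accuracy strictly improves.

**Pipeline.** Candidate voxels must have SUV > 1, HU in [−300, 200] and
non-zero PET busyness below a cap; classified voxels pass a 0.5 cm³
connected-component filter, slice-wise disc (r = 2) dilation–closing–
hole-fill–erosion, and a final re-application of the HU window.
SUV-threshold baselines (absolute 2.5, 20–50 % of max) and an
intensity-only HU/SUV KNN are included for comparison.

**Evaluation.** Multiple observer masks are fused by STAPLE
(expectation-maximization of a per-voxel truth probability and per-rater
sensitivity/specificity); segmentations are scored with
probability-weighted sensitivity, specificity and Dice, which reduce to
the classical formulas for binary truth.

## Worked example

```python
import numpy as np
from texseg import (easy_phantom_spec, generate_phantom, resample_pet_to_ct,
                    FeatureExtractor, compute_snr, staple, weighted_metrics,
                    threshold_baseline, concordance_index)

case = generate_phantom(easy_phantom_spec(seed=3))
print(compute_snr(case.ct, case.liver_roi()).snr)   # 6.00 (calibrated)

pet_ct = resample_pet_to_ct(case.pet, case.ct)
ex = FeatureExtractor(case.ct, pet_ct)
vox = np.argwhere(case.tumor_mask)[::400][:3]
print(ex.features_at(vox, ["ct_consistency", "pet_coarseness", "pet_mean"]))

truth = staple(case.observers)
seg = threshold_baseline(pet_ct, "percent", 0.30)
print(weighted_metrics(truth.probabilities, seg))
```

prints (seed 3):

```
liver CT SNR: 6.00
ct_consistency: 0.255, 0.948, 0.997
pet_coarseness: 7.718, 6.744, 13.068
pet_mean: 1.823, 2.937, 3.428
STAPLE rater sensitivities: [0.882 0.877 0.882]
observer concordance: 0.574
30%-max-SUV baseline vs consensus: Dice 0.723, sensitivity 0.891
```

The consistency values show exactly the intended contrast: near 1 in
windows of homogeneous uptake, low where the tumor's heterogeneous
texture mixes grey levels.  The STAPLE estimates recover the simulated
observers' ~0.9 sensitivity, and the 30 %-of-max baseline scores Dice
0.72 against their consensus on this high-contrast case.

The same steps are available from the shell:

```bash
texseg phantom --preset easy --seed 3 --out case1
texseg prep --pet case1/pet.nii.gz --ct case1/ct.nii.gz --out case1/pet_on_ct.nii.gz
texseg segment --pet case1/pet_on_ct.nii.gz --ct case1/ct.nii.gz \
       --model model.json --out case1/seg.nii.gz
texseg evaluate --segment case1/seg.nii.gz \
       --masks case1/observer_0.nii.gz --masks case1/observer_1.nii.gz \
       --masks case1/observer_2.nii.gz --out case1/report.json
```

Training a DTKNN end-to-end (`texseg train`) consumes ROI sample tables
built with `texseg.sampling.roi_slice_samples`, which averages window
features per ROI slice after a 7 mm margin erosion.

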