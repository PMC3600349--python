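# Methods

This note documents the models, parameter choices and numerical
conventions of `texseg`, and what the synthetic phantoms do and do not
establish.

## Voxel classification model

A voxel is represented by 43 window features (22 CT, 21 PET; Tamura
directionality is computed for CT only, since the coarse PET in-plane
resolution carries no reliable orientation signal).  All windows are
7×7×3 voxels (rows × columns × slices = 7×7 in-plane, 3 slices), chosen
so the physical extent is roughly isotropic at 0.98×0.98×2.5 mm CT
spacing.  Borders are handled by nearest-edge replication.

Quantization: CT intensities are clipped to a HU window (default
[−1000, 1000], configurable — it spans lung to bone) and binned into 256
levels; PET is binned at a fixed 0.05 SUV per level with a 512-level cap
(25.6 SUV), which bounds co-occurrence matrix size.  Co-occurrence
matrices are accumulated over the 13 unique adjoining-voxel offsets
(both directions, symmetrized, normalized); a config switch restricts to
the four classical in-plane directions.  Per window, only occurring grey
levels are materialized, but every feature is evaluated on the original
level values, so compaction never changes a feature value.  The
consistency feature uses the full level count N_g of the quantization
rule as its cosine period.

Grey-tone difference (NGTDM) features follow Amadasun–King with one
modification: the per-level deviation sums s(i), the level differences
(i−j) and the cross terms |i·pᵢ − j·pⱼ| are divided by the mean grey
level of the window.  This makes coarseness, N-contrast and busyness
exactly invariant under multiplicative intensity rescaling (equivalently
under proportional re-binning), which is the property required of them;
the precise published form of that normalization is not reproduced here,
so this simplest variant is used and exposed as a documented convention.
A uniform window returns the coarseness sentinel 10⁶ (the reciprocal of
the ε = 10⁻⁶ guarding the denominator) and zero contrast/busyness.

Other numerical conventions: standard deviations use the sample (n−1)
denominator everywhere; skewness/kurtosis are population moment ratios
with kurtosis reported as excess, and both are defined as 0 for
zero-variance windows (a relative threshold of 10⁻¹² times the mean
guards against float round-off); entropy is base 2 with 0·log 0 = 0;
correlation of a zero-variance co-occurrence marginal is 0; the
left–right symmetry ratio mirrors the *whole volume* across its
mid-sagittal plane (the last array axis) and guards the division with a
one-unit offset after shifting CT to non-negative values; Tamura
directionality uses per-slice central-difference gradients and the mean
resultant length of the magnitude-weighted doubled-angle distribution.

## DTKNN training

Training samples are ROI slices: each labelled region is eroded by a
7 mm margin (ellipsoidal erosion in voxel units) so window features are
not contaminated by boundary gradients, and window features are averaged
per axial slice, at most 20 evenly spaced voxels per slice.  Lung labels
are excluded from training (air is removed by the HU prefilter at
inference anyway).

Each tree node performs an exhaustive search over all feature subsets of
size 1–3, scoring each by the AUC90 of the leave-one-out ROC of a k = 7
KNN on standardized features.  The ROC is traced over the nine possible
abnormal-vote thresholds.  Ties in AUC90 — frequent on well-separated
data, where many subsets reach the 0.1 ceiling — are broken by the full
AUC, then by smaller subset size, then by lexicographic name order.  The
pure size/name rule without the AUC step is deliberately not used: when
dozens of subsets saturate AUC90, alphabetical order selects features
with no regard to their margin, and transfer from slice-averaged
training samples to single-voxel classification degrades badly.

Samples are routed into branches by each node's *leave-one-out*
prediction (resubstitution with k = 7 self-matching would distort the
splits).  A branch receives a child node only if it contains
misclassified samples, both classes keep at least 4 samples there, and
attaching the child strictly improves whole-tree leave-one-out accuracy.
Distance ties at the k-th neighbour are resolved by stable sample order;
if a node holds fewer than k samples, k is lowered to the largest odd
available count.  The candidate feature pool entering the search can be
capped (ranked by single-feature AUC90, then AUC); the end-to-end runs
and the acceptance script cap it at 12 to keep the cubic subset search
fast — the full 43-feature search remains available.

## Segmentation pipeline

Fixed stage order: (1) prefilter — SUV > 1, HU ∈ [−300, 200], PET
busyness non-zero and < 0.8 (the busyness cap is configurable; under the
mean-normalized NGTDM scaling used here phantom busyness values are far
below 0.8, so the gate is inert on synthetic data and acts only as a
guard); (2) DTKNN classification of candidate voxels; (3) removal of
26-connected components below 0.5 cm³ (voxel volume = product of mm
spacings / 1000); (4) slice-wise morphology with a radius-2 disc —
dilation, closing with the same disc, per-slice hole filling, erosion —
recovering homogeneous tumor cores that gradient-seeking features miss;
(5) re-application of the HU window, so no final voxel lies in bone or
air.  The disc operations are 2-D (transverse plane) and hole filling is
per-slice, consistent with the 2-D disc pipeline.

## Evaluation

STAPLE is the basic EM form: a stationary global prior equal to the mean
foreground fraction of the inputs, no spatial regularization, tolerance
10⁻⁶ on the maximum posterior change, 100-iteration cap.  Per-rater
sensitivities/specificities are re-estimated against the posterior each
iteration; the observed-data log-likelihood is tracked and is
non-decreasing.  The implementation agrees with the SimpleITK STAPLE
filter to ~10⁻⁷ mean absolute posterior difference on test cases.

Weighted metrics: with truth probabilities P(T) and a segment Ω₊,
sensitivity = ΣΩ₊P(T) / ΣΩP(T), specificity = ΣΩ₋P(F) / (ΣΩ₋P(F) +
ΣΩ₊P(F)), Dice = 2·ΣΩ₊P(T) / (ΣΩP(T) + |Ω₊|).  Undefined cases (e.g. an
all-zero truth) return NaN sentinels, never a silent 0.  The observer
concordance index is the mean pairwise Jaccard overlap; an
all-mask intersection-over-union variant is available by flag.

## The phantom

The generator emulates a miniature thorax on a 28×80×96 CT grid
(0.98×0.98×2.5 mm; ~70×78×94 mm): a soft-tissue body (20 HU, 0.7 SUV)
containing two air-filled lungs (−780 HU, 0.25 SUV), liver (60 HU,
2.2 SUV), heart (45 HU, 2.0 SUV), spleen, trapezius muscle, and an
ellipsoidal tumor of ~3 cm diameter inside the right lung.  Organs are
embedded in soft tissue so that — as in a real thorax — only lung
interfaces present the sharp air/tissue step.  The tumor interior is a
two-level (thresholded Gaussian random field) texture alternating
between its SUV/HU range bounds at a 4 mm correlation length; this gives
the coarseness/busyness structure that the grey-tone features must
detect.

PET is painted independently on its native 3.27×3.9×3.9 mm grid,
blurred by a 7 mm FWHM Gaussian (scanner point-spread), and resampled to
the CT grid by trilinear interpolation at processing time.  White noise
is added per modality so that the margin-eroded liver ROI reaches the
target SNR (mean/σ): CT 3.7 (the quality-control cutoff) and PET 7.56
(the typical scanner value) by default; the realized noise is
renormalized inside the ROI so the measured SNR matches the target
rather than fluctuating with the draw.  Two kinds of realistic
variability are added: per-case intensity jitter (lognormal σ = 0.10 on
mean SUV, ±5 HU on mean HU — interpatient/interscanner variation) and a
slow within-case drift (6 HU CT bias field, 10 % multiplicative PET
gradient, 25 mm correlation) standing in for uptake gradients and bias
fields.  Without this variability, slice-averaged training samples
become perfectly separable in dozens of features and subset selection
degenerates into tie-breaking.

Observer contours are simulated by flipping labels at exact per-region
counts matching the requested sensitivity (0.9) and specificity (0.995
for whole-volume raters), with flip sites drawn from the top quantiles
of a smooth Gaussian field so errors form plausible blobs; a 27-voxel
majority filter tidies blob boundaries, and the pre-filter flip counts
are iterated so the post-filter rates still match the request (within
~1 %).  Independent i.i.d. flips were rejected: a majority filter erases
isolated flips almost completely, so rates could never be recovered.

Two study presets: the *easy* phantom (tumor SUV 4–9 on the default
geometry, CT SNR 6) and the *overlapping* phantom (tumor SUV 1.2–3.2 and
HU 30–70, bracketing liver/heart intensities, with a coarse 6 mm texture
and lower noise) where intensity alone cannot separate tumor from organ
and only texture can.

**What passing phantom tests does not show.**  The phantom has
piecewise-ellipsoidal anatomy, uncorrelated CT/PET texture fields,
stationary white noise and no respiratory motion, scatter or
reconstruction artifacts; organ texture is far more homogeneous than
real parenchyma.  Performance numbers on phantoms therefore validate the
*machinery* (feature arithmetic, selection, tree growth, pipeline
plumbing, metric definitions), not clinical segmentation accuracy.

## Problem sizes and variability

End-to-end runs train on 5 phantom cases (≈ 260–280 slice samples, ~30
abnormal) and evaluate on 3 held-out cases per scenario; averaging over
3 test cases damps the case-to-case spread of a single small tumor.  At
this scale the easy-phantom Dice against the true mask is ≈ 0.72–0.87
across seeds, and the texture tree beats the intensity-only HU/SUV KNN
on the overlapping phantom on average, though the gap at an individual
seed can be small or occasionally invert — the subset chosen from ~30
abnormal samples is itself seed-dependent, mirroring the known
instability of decision trees under small training sets.  The
leave-one-training-case-out retraining variability reported by the
acceptance script quantifies exactly this.

## Known limitations

- The slice-averaged training samples have much lower variance than the
  single-voxel features the tree later classifies; extrapolation at
  organ boundaries (windows straddling air) is the dominant
  false-positive source, concentrated at lung interfaces and organ
  edges.
- The ~3 cm tumor yields only ~6 eroded slices per case; subset
  selection saturates easily and depends on the tie-break rules
  documented above.
- The exact published normalization of the scale-invariant NGTDM
  variant is unavailable; the mean-level normalization used here is a
  documented stand-in with the required invariance.
- Whether Tamura directionality should use 3-D gradients is an open
  choice; 2-D in-plane gradients are used.  The left–right mirror is
  body-level (whole volume), not window-level.
- STAPLE is the spatially unregularized form; raters with strongly
  correlated errors would bias the consensus.
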