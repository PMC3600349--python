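"""Feature bank: co-occurrence, NGTDM, first-order, structural and Tamura
features, plus the sliding-map machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texseg.features import (
    COARSENESS_MAX,
    CooccurrenceMatrix,
    FeatureExtractor,
    consistency,
    feature_names,
    first_order,
    haralick_features,
    lr_symmetry_ratio,
    morphological_gradient,
    ngtdm,
    ngtdm_features,
    sgldm,
    tamura_contrast,
    tamura_directionality,
)
from texseg.features.cooccurrence import OFFSETS_3D, OFFSETS_INPLANE
from texseg.features.maps import (
    FIRST_ORDER_NAMES,
    NGTDM_NAMES,
    SGLDM_NAMES,
)
from texseg.volumes import ct_rule, erode_roi_margin, pet_rule, quantize

# -- co-occurrence ---------------------------------------------------


def brute_force_glcm(patch, offsets):
    """Independent triple-loop co-occurrence accumulation (oracle)."""
    patch = np.asarray(patch)
    levels = np.unique(patch)
    k = levels.size
    idx = {v: i for i, v in enumerate(levels)}
    P = np.zeros((k, k))
    for dz, dy, dx in offsets:
        for z in range(patch.shape[0]):
            for y in range(patch.shape[1]):
                for x in range(patch.shape[2]):
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if 0 <= z2 < patch.shape[0] and 0 <= y2 < patch.shape[1] and 0 <= x2 < patch.shape[2]:
                        a, b = idx[patch[z, y, x]], idx[patch[z2, y2, x2]]
                        P[a, b] += 1
                        P[b, a] += 1
    return P / P.sum(), levels


def test_strip_cooccurrence_hand_count():
    """[0,1,0,1] with a single x-offset has three symmetric 0-1 pairs."""
    C = sgldm(np.array([[[0, 1, 0, 1]]]), offsets=[(0, 0, 1)], n_levels=2)
    np.testing.assert_allclose(C.P, [[0, 0.5], [0.5, 0]], atol=1e-12)


def test_constant_patch_all_mass_on_diagonal():
    C = sgldm(np.full((3, 3, 3), 5), n_levels=256)
    h = haralick_features(C)
    assert h["energy"] == pytest.approx(1.0)
    assert h["entropy"] == pytest.approx(0.0)
    assert h["s_contrast"] == pytest.approx(0.0)
    assert h["homogeneity"] == pytest.approx(1.0)
    assert h["consistency"] == pytest.approx(1.0)


@pytest.mark.parametrize("offsets", [OFFSETS_3D, OFFSETS_INPLANE])
def test_sgldm_matches_brute_force(rng, offsets):
    patch = rng.integers(0, 6, (3, 5, 5))
    C = sgldm(patch, offsets=offsets)
    P_ref, levels_ref = brute_force_glcm(patch, offsets)
    np.testing.assert_array_equal(C.levels, levels_ref)
    np.testing.assert_allclose(C.P, P_ref, atol=1e-12)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_cooccurrence_invariants(seed):
    patch = np.random.default_rng(seed).integers(0, 8, (3, 6, 6))
    C = sgldm(patch)
    assert np.all(C.P >= 0)
    assert C.P.sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(C.P, C.P.T, atol=1e-12)
    c = consistency(C)
    assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12
    h = haralick_features(C)
    assert 0 < h["energy"] <= 1.0 + 1e-12
    assert h["entropy"] >= -1e-12
    assert 0 < h["homogeneity"] <= 1.0 + 1e-12


def test_haralick_two_level_oracle():
    """P(0,1)=P(1,0)=0.5: direct evaluation of every second-order formula."""
    C = CooccurrenceMatrix(np.array([[0, 0.5], [0.5, 0]]), [0, 1], 2)
    h = haralick_features(C)
    assert h["energy"] == pytest.approx(0.5, abs=1e-9)
    assert h["entropy"] == pytest.approx(1.0, abs=1e-9)  # bits
    assert h["dissimilarity"] == pytest.approx(1.0, abs=1e-9)
    assert h["s_contrast"] == pytest.approx(1.0, abs=1e-9)
    assert h["sum_average"] == pytest.approx(1.0, abs=1e-9)
    assert h["correlation"] == pytest.approx(-1.0, abs=1e-9)


def test_consistency_reference_cases():
    diag = CooccurrenceMatrix(np.eye(3) / 3, [0, 1, 2], 3)
    assert consistency(diag) == pytest.approx(1.0, abs=1e-9)
    anti = CooccurrenceMatrix(np.array([[0, 0.5], [0.5, 0]]), [0, 2], 4)
    assert consistency(anti) == pytest.approx(-1.0, abs=1e-9)
    uniform = CooccurrenceMatrix(np.full((4, 4), 1 / 16), [0, 1, 2, 3], 4)
    assert consistency(uniform) == pytest.approx(0.0, abs=1e-9)


def test_consistency_bounds_and_diagonal_condition(rng):
    for _ in range(10):
        patch = rng.integers(0, 10, (3, 5, 5))
        c = consistency(sgldm(patch, n_levels=16))
        assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12


def test_cluster_shade_sign_flips_under_level_reflection(rng):
    """Mirroring grey levels (i -> max-i) negates the third central moment."""
    patch = rng.integers(0, 7, (3, 5, 5))
    C = sgldm(patch)
    h = haralick_features(C)
    Cm = sgldm(patch.max() - patch)
    hm = haralick_features(Cm)
    assert hm["cluster_shade"] == pytest.approx(-h["cluster_shade"], abs=1e-9)


# -- NGTDM -----------------------------------------------------------


def test_ngtdm_constant_patch_sentinels():
    f = ngtdm_features(ngtdm(np.full((3, 7, 7), 9)))
    assert f["coarseness"] == COARSENESS_MAX
    assert f["n_contrast"] == 0.0
    assert f["busyness"] == 0.0


def test_ngtdm_scale_invariance(rng):
    patch = rng.integers(1, 30, (3, 7, 7))
    f1 = ngtdm_features(ngtdm(patch))
    f2 = ngtdm_features(ngtdm(patch * 2))
    for k in f1:
        assert f2[k] == pytest.approx(f1[k], rel=1e-6)


def test_ngtdm_invariant_under_proportional_binning(rng):
    from texseg.volumes import QuantizationRule, Volume

    suv = rng.uniform(0.5, 6.0, (3, 7, 7))
    v1 = Volume(suv, (1, 1, 1))
    v2 = Volume(suv * 2, (1, 1, 1))
    q1 = quantize(v1, pet_rule(bin_width=0.05)).data
    q2 = quantize(v2, pet_rule(bin_width=0.10)).data
    f1 = ngtdm_features(ngtdm(q1))
    f2 = ngtdm_features(ngtdm(q2))
    for k in f1:
        assert f2[k] == pytest.approx(f1[k], rel=1e-6)


def test_coarse_blocks_coarser_than_checkerboard():
    idx = np.indices((3, 8, 8)).sum(axis=0)
    checker = (idx % 2) * 10 + 1
    blocks = np.ones((3, 8, 8))
    blocks[:, :, 4:] = 11
    fc = ngtdm_features(ngtdm(checker))
    fb = ngtdm_features(ngtdm(blocks))
    assert fb["coarseness"] > fc["coarseness"]


# -- first order -----------------------------------------------------


def test_first_order_symmetric_set():
    f = first_order(np.array([1.0, 2.0, 3.0, 4.0]))
    assert f["mean"] == pytest.approx(2.5)
    assert f["median"] == pytest.approx(2.5)
    assert f["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_first_order_constant_window_degenerate():
    f = first_order(np.full(21, 3.3))
    assert f["std"] == 0.0 and f["skewness"] == 0.0 and f["kurtosis"] == 0.0


def test_first_order_outlier_positive_skew():
    f = first_order(np.array([0.0, 0.0, 0.0, 10.0]))
    # moments computed directly: m3 > 0 for a high outlier
    assert f["skewness"] > 0


# -- structural ------------------------------------------------------


def test_morph_gradient_of_constant_is_zero():
    assert np.all(morphological_gradient(np.full((5, 9, 9), 4.2)) == 0)


def test_morph_gradient_support_is_radius2_ball():
    from skimage.morphology import ball

    vol = np.zeros((9, 9, 9))
    vol[4, 4, 4] = 1.0
    grad = morphological_gradient(vol)
    expected = np.zeros_like(vol, dtype=bool)
    expected[2:7, 2:7, 2:7] = ball(2).astype(bool)
    np.testing.assert_array_equal(grad > 0, expected)


def test_lr_symmetry_of_mirror_symmetric_volume(rng):
    half = rng.uniform(0, 100, (4, 6, 3))
    vol = np.concatenate([half, half[:, :, ::-1]], axis=2)
    np.testing.assert_allclose(lr_symmetry_ratio(vol), 1.0, atol=1e-12)


# -- Tamura ----------------------------------------------------------


def test_tamura_degenerate_cases():
    assert tamura_contrast(np.full(10, 2.0)) == 0.0
    assert tamura_directionality(np.zeros((3, 7, 7))) == 0.0


def test_tamura_contrast_symmetric_bernoulli():
    # {0 x n, 1 x n}: alpha4 = 1, so contrast equals the (population) std
    v = np.array([0.0] * 8 + [1.0] * 8)
    assert tamura_contrast(v) == pytest.approx(0.5, abs=1e-12)


def test_tamura_directionality_maximal_for_ramp():
    ramp = np.tile(np.arange(7.0), (3, 7, 1))
    assert tamura_directionality(ramp) == pytest.approx(1.0, abs=1e-9)


# -- maps ------------------------------------------------------------


def test_feature_name_bank_is_43():
    names = feature_names()
    assert len(names) == 43
    assert len([n for n in names if n.startswith("ct_")]) == 22
    assert len([n for n in names if n.startswith("pet_")]) == 21
    assert "pet_directionality" not in names


def test_unknown_feature_rejected(small_extractor):
    with pytest.raises(KeyError):
        small_extractor.features_at([(2, 5, 5)], ["ct_wavelet"])
    with pytest.raises(KeyError):
        small_extractor.features_at([(2, 5, 5)], ["pet_directionality"])


def test_mean_map_of_constant_volume_is_constant():
    from texseg.volumes import CT_HU, PET_SUV, Volume

    ct = Volume(np.full((4, 10, 10), 50.0), (2.5, 1, 1), modality=CT_HU)
    pet = Volume(np.full((4, 10, 10), 2.0), (2.5, 1, 1), modality=PET_SUV)
    maps = FeatureExtractor(ct, pet).maps(["ct_mean", "pet_mean"])
    np.testing.assert_allclose(maps["ct_mean"], 50.0, atol=1e-9)
    np.testing.assert_allclose(maps["pet_mean"], 2.0, atol=1e-9)


def test_maps_are_deterministic(small_extractor):
    vox = np.array([[3, 10, 10], [4, 15, 20]])
    a = small_extractor.features_at(vox)
    b = small_extractor.features_at(vox)
    for n in a:
        np.testing.assert_array_equal(a[n], b[n])


def test_map_values_equal_direct_window_computation(small_case, small_extractor):
    """Map/kernel equivalence at interior voxels, against an independent
    re-computation from the raw volumes."""
    from texseg.volumes import resample_pet_to_ct

    ct = small_case.ct
    pet = resample_pet_to_ct(small_case.pet, small_case.ct)
    qct = quantize(ct, ct_rule()).data
    qpet = quantize(pet, pet_rule()).data
    grad = {"ct": morphological_gradient(ct.data), "pet": morphological_gradient(pet.data)}
    ratio = {"ct": lr_symmetry_ratio(ct.data), "pet": lr_symmetry_ratio(pet.data)}
    raw = {"ct": ct.data, "pet": pet.data}
    quant = {"ct": (qct, 256), "pet": (qpet, 512)}

    rng = np.random.default_rng(5)
    shape = ct.data.shape
    vox = np.column_stack(
        [
            rng.integers(1, shape[0] - 1, 20),
            rng.integers(3, shape[1] - 3, 20),
            rng.integers(3, shape[2] - 3, 20),
        ]
    )
    got = small_extractor.features_at(vox)
    for i, (z, y, x) in enumerate(vox):
        win = (slice(z - 1, z + 2), slice(y - 3, y + 4), slice(x - 3, x + 4))
        for mod in ("ct", "pet"):
            fo = first_order(raw[mod][win])
            for k in FIRST_ORDER_NAMES:
                assert got[f"{mod}_{k}"][i] == pytest.approx(fo[k], abs=1e-9), f"{mod}_{k}"
            q, ng = quant[mod]
            h = haralick_features(sgldm(q[win], n_levels=ng))
            for k in SGLDM_NAMES:
                assert got[f"{mod}_{k}"][i] == pytest.approx(h[k], rel=1e-9, abs=1e-12), f"{mod}_{k}"
            nf = ngtdm_features(ngtdm(q[win]))
            for k in NGTDM_NAMES:
                assert got[f"{mod}_{k}"][i] == pytest.approx(nf[k], rel=1e-9, abs=1e-12), f"{mod}_{k}"
            assert got[f"{mod}_morph_gradient"][i] == pytest.approx(grad[mod][z, y, x], abs=1e-9)
            assert got[f"{mod}_morph_gradient_std"][i] == pytest.approx(
                first_order(grad[mod][win])["std"], abs=1e-9
            )
            assert got[f"{mod}_lr_symmetry"][i] == pytest.approx(
                float(np.mean(ratio[mod][win])), abs=1e-9
            )
            assert got[f"{mod}_t_contrast"][i] == pytest.approx(
                tamura_contrast(raw[mod][win]), abs=1e-9
            )
        assert got["ct_directionality"][i] == pytest.approx(
            tamura_directionality(raw["ct"][win]), abs=1e-9
        )


def test_consistency_higher_in_homogeneous_liver_than_tumor(small_case, small_extractor):
    """Occurrence homogeneity should drop inside the textured tumor."""
    spacing = small_case.ct.spacing
    liver = erode_roi_margin(small_case.organ_mask("liver"), 5.0, spacing)
    tumor = erode_roi_margin(small_case.tumor_mask, 4.0, spacing)
    lv = np.argwhere(liver)[::4][:60]
    tv = np.argwhere(tumor)[::2][:60]
    liver_c = small_extractor.features_at(lv, ["ct_consistency"])["ct_consistency"]
    tumor_c = small_extractor.features_at(tv, ["ct_consistency"])["ct_consistency"]
    assert np.mean(liver_c) > np.mean(tumor_c)
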