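"""Feature extractor checks: brute-force oracle agreement on random ROIs,
hand-computed examples, and the protocol's invariances."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_roi, random_roi
from oracles import (RLM_KEYMAP, naive_glcm, naive_glcm_features,
                     naive_glrlm, naive_glszm, naive_ngtdm,
                     naive_ngtdm_features, naive_rlm_features)
from radstab.grids import BinaryMask, ImageGrid
from radstab.preprocess import PreprocessConfig, discretize
from radstab.radiomic_features import (ANGLES_2D, CATEGORY_COUNTS,
                                       FEATURE_NAMES, build_glcm,
                                       build_glrlm, build_glszm, build_ngtdm,
                                       extract_all, firstorder_features,
                                       glcm_features, glrlm_features,
                                       glszm_features, ngtdm_features,
                                       shape_features)

RNG = np.random.default_rng(20260920)
RANDOM_ROIS = [random_roi(RNG) for _ in range(20)]


# --------------------------------------------------------------------------
# texture matrices vs brute-force enumeration

@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_glcm_matches_pair_enumeration(roi):
    for mat in build_glcm(roi):
        ref = naive_glcm(roi.levels, roi.ng, mat.offset)
        np.testing.assert_allclose(mat.table, ref, atol=1e-12)
        assert mat.table.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(mat.table, mat.table.T, atol=0)


def test_glcm_toy_example():
    # 2x2 levels [[1,1],[1,2]], horizontal d=1: pairs (1,1),(1,2)
    roi = make_roi([[1, 1], [1, 2]])
    mat = [m for m in build_glcm(roi) if m.offset == (0, 1)][0]
    np.testing.assert_allclose(mat.table,
                               [[0.5, 0.25], [0.25, 0.0]], atol=1e-12)
    feats = glcm_features([mat])
    assert feats["MaximumProbability"] == pytest.approx(0.5)
    assert feats["JointEnergy"] == pytest.approx(0.375)


def test_glcm_checkerboard_diagonal_zero():
    levels = np.indices((6, 6)).sum(axis=0) % 2 + 1
    roi = make_roi(levels)
    for mat in build_glcm(roi):
        if mat.offset in ((0, 1), (-1, 0)):
            assert np.all(np.diag(mat.table) == 0)


@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_glcm_features_match_naive_formulas(roi):
    mats = build_glcm(roi)
    ours = glcm_features(mats)
    per_angle = [naive_glcm_features(m.table) for m in mats]
    for name, value in ours.items():
        ref = np.mean([f[name] for f in per_angle])
        np.testing.assert_allclose(value, ref, rtol=1e-9, atol=1e-12)


def test_glcm_single_level_limits():
    roi = make_roi(np.ones((5, 5), dtype=int))
    feats = glcm_features(build_glcm(roi))
    assert feats["Contrast"] == 0
    assert feats["JointEntropy"] == 0
    assert feats["MaximumProbability"] == 1
    assert feats["Correlation"] == 1
    assert feats["Imc1"] == 0 and feats["Imc2"] == 0
    assert feats["InverseVariance"] == 0


@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_glrlm_matches_run_scan(roi):
    for mat in build_glrlm(roi):
        ref = naive_glrlm(roi.levels, roi.ng, mat.offset)
        np.testing.assert_allclose(mat.table, ref[:, :mat.table.shape[1]],
                                   atol=0)
        assert ref[:, mat.table.shape[1]:].sum() == 0
        # total runs equals the matrix mass
        assert mat.table.sum() == ref.sum()


def test_glrlm_row_example_and_single_run():
    roi = make_roi([[1, 1, 1, 2]])
    mat = [m for m in build_glrlm(roi) if m.offset == (0, 1)][0]
    assert mat.table[0, 2] == 1  # level 1, run length 3
    assert mat.table[1, 0] == 1  # level 2, run length 1
    assert mat.table.sum() == 2

    n = 7
    const = make_roi(np.ones((1, n), dtype=int))
    feats = glrlm_features(build_glrlm(const), n_px=n)
    # horizontal: one run of length n (LRE n^2, pct 1/n); the other three
    # directions see n runs of length 1 (LRE 1, pct 1); features average
    assert feats["LongRunEmphasis"] == pytest.approx((n ** 2 + 3) / 4)
    assert feats["RunPercentage"] == pytest.approx((1 / n + 3) / 4)


@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_glrlm_features_match_naive_formulas(roi):
    mats = build_glrlm(roi)
    n_px = int(roi.mask.sum())
    ours = glrlm_features(mats, n_px)
    per_angle = [naive_rlm_features(m.table, n_px) for m in mats]
    keymap = RLM_KEYMAP["run"]
    for short, name in keymap.items():
        ref = np.mean([f[short] for f in per_angle])
        np.testing.assert_allclose(ours[name], ref, rtol=1e-9, atol=1e-12)


def test_checkerboard_runs_all_length_one():
    levels = np.indices((6, 6)).sum(axis=0) % 2 + 1
    roi = make_roi(levels)
    for mat in build_glrlm(roi):
        if mat.offset in ((0, 1), (-1, 0)):
            assert mat.table.shape[1] == 1  # no run longer than 1


@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_glszm_matches_flood_fill(roi):
    mat = build_glszm(roi)
    ref = naive_glszm(roi.levels, roi.ng)
    np.testing.assert_allclose(mat.table, ref[:, :mat.table.shape[1]], atol=0)
    assert ref[:, mat.table.shape[1]:].sum() == 0


def test_glszm_examples():
    roi = make_roi([[1, 1], [2, 2]])
    mat = build_glszm(roi)
    assert mat.table[0, 1] == 1 and mat.table[1, 1] == 1
    assert mat.table.sum() == 2

    n = 4
    const = make_roi(np.ones((n, n), dtype=int))
    feats = glszm_features(build_glszm(const), n_px=n * n)
    assert feats["ZonePercentage"] == pytest.approx(1 / (n * n))


@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_glszm_features_match_naive_formulas(roi):
    mat = build_glszm(roi)
    n_px = int(roi.mask.sum())
    ours = glszm_features(mat, n_px)
    ref = naive_rlm_features(mat.table, n_px)
    for short, name in RLM_KEYMAP["zone"].items():
        np.testing.assert_allclose(ours[name], ref[short],
                                   rtol=1e-9, atol=1e-12)


@pytest.mark.parametrize("roi", RANDOM_ROIS)
def test_ngtdm_matches_pixel_scan(roi):
    ours = build_ngtdm(roi).table
    ref = naive_ngtdm(roi.levels, roi.ng)
    np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-12)
    ours_f = ngtdm_features(build_ngtdm(roi))
    ref_f = naive_ngtdm_features(ref)
    for name in ours_f:
        np.testing.assert_allclose(ours_f[name], ref_f[name],
                                   rtol=1e-9, atol=1e-12)


def test_ngtdm_centre_outlier_hand_computed():
    levels = np.ones((3, 3), dtype=int)
    levels[1, 1] = 3
    roi = make_roi(levels)
    tab = build_ngtdm(roi).table
    # 8 edge pixels: one neighbour differs; centre: all 8 neighbours are 1
    # corner pixels have 3 neighbours (one is the centre 3): |1 - 5/3|
    # edge-centre pixels have 5 neighbours: |1 - 7/5|
    s1 = 4 * abs(1 - 5 / 3) + 4 * abs(1 - 7 / 5)
    assert tab[0, 2] == pytest.approx(s1)
    assert tab[2, 2] == pytest.approx(abs(3 - 1))


def test_ngtdm_constant_roi_caps_coarseness():
    roi = make_roi(np.ones((4, 4), dtype=int))
    feats = ngtdm_features(build_ngtdm(roi))
    assert feats["Coarseness"] == 1e6
    assert feats["Contrast"] == 0


# --------------------------------------------------------------------------
# first-order and shape

def test_firstorder_hand_examples():
    roi = make_roi(np.array([[1, 2, 3, 4]]))
    f = firstorder_features(roi)
    assert f["Mean"] == pytest.approx(2.5)
    assert f["Variance"] == pytest.approx(1.25)
    assert f["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))

    const = make_roi(np.full((3, 3), 2, dtype=int))
    f = firstorder_features(const)
    assert f["Entropy"] == 0 and f["Uniformity"] == 1
    assert f["Variance"] == 0 and f["Range"] == 0

    two_bins = make_roi(np.array([[1, 1, 2, 2]]))
    f = firstorder_features(two_bins)
    assert f["Entropy"] == pytest.approx(1.0)
    assert f["Uniformity"] == pytest.approx(0.5)


def test_shape_square_geometry():
    msk = np.zeros((20, 20), dtype=bool)
    msk[5:15, 5:15] = True
    f = shape_features(BinaryMask(msk))
    assert f["VoxelVolume"] == pytest.approx(100.0)
    assert f["Maximum2DDiameterSlice"] == pytest.approx(np.sqrt(162))
    assert f["Elongation"] == pytest.approx(1.0)


def test_shape_disc_sphericity_vs_analytic_cylinder():
    n, r = 64, 20.0
    rr, cc = np.mgrid[0:n, 0:n]
    centre = (n - 1) / 2
    msk = BinaryMask(np.hypot(rr - centre, cc - centre) <= r)
    f = shape_features(msk)
    v = np.pi * r ** 2 * 1.0
    sa = 2 * np.pi * r ** 2 + 2 * np.pi * r * 1.0
    analytic = (36 * np.pi * v ** 2) ** (1 / 3) / sa
    assert f["Sphericity"] == pytest.approx(analytic, rel=0.05)


def test_shape_rotation_invariance_on_lattice():
    rng = np.random.default_rng(7)
    blob = np.zeros((30, 30), dtype=bool)
    blob[8:20, 10:25] = True
    blob[5:9, 12:18] = True
    f0 = shape_features(BinaryMask(blob))
    f90 = shape_features(BinaryMask(np.rot90(blob)))
    for name in ("MajorAxisLength", "Perimeter", "Sphericity"):
        assert f0[name] == pytest.approx(f90[name], rel=1e-9)


def test_shape_spacing_scaling_laws():
    msk = np.zeros((20, 20), dtype=bool)
    msk[5:15, 7:14] = True
    f1 = shape_features(BinaryMask(msk, spacing=(1, 1)))
    f2 = shape_features(BinaryMask(msk, spacing=(2, 2)))
    assert f2["Perimeter"] == pytest.approx(2 * f1["Perimeter"])
    assert f2["Maximum2DDiameterSlice"] == pytest.approx(
        2 * f1["Maximum2DDiameterSlice"])
    assert f2["MeshVolume"] == pytest.approx(4 * f1["MeshVolume"])


def test_shape_rejects_multi_component():
    msk = np.zeros((10, 10), dtype=bool)
    msk[1:3, 1:3] = True
    msk[7:9, 7:9] = True
    with pytest.raises(ValueError):
        shape_features(BinaryMask(msk))


# --------------------------------------------------------------------------
# full extraction

def _lesion(seed=0):
    from radstab.synthetic_cohort import LUNG_PRESET, make_lesion
    return make_lesion(LUNG_PRESET, seed=seed)


def test_extract_all_partition_and_finiteness():
    img, msk = _lesion()
    feats = extract_all(img, msk)
    assert list(feats) == list(FEATURE_NAMES)
    counts = {}
    for name in feats:
        counts[name.split("_")[0]] = counts.get(name.split("_")[0], 0) + 1
    assert counts == CATEGORY_COUNTS
    assert (counts["firstorder"], counts["shape"], counts["glcm"],
            counts["glszm"], counts["glrlm"], counts["ngtdm"]) == \
        (18, 12, 22, 16, 16, 5)
    assert all(np.isfinite(v) for v in feats.values())


def test_extract_all_deterministic():
    img, msk = _lesion()
    assert extract_all(img, msk) == extract_all(img, msk)


def test_extract_all_hu_shift_invariance():
    img, msk = _lesion()
    shifted = ImageGrid(img.values + 100.0, img.spacing)
    f0 = extract_all(img, msk)
    f1 = extract_all(shifted, msk)
    for name in FEATURE_NAMES:
        cat = name.split("_")[0]
        if cat in ("glcm", "glszm", "glrlm", "ngtdm") or name in (
                "firstorder_Entropy", "firstorder_Uniformity"):
            assert f1[name] == pytest.approx(f0[name], rel=1e-12), name
    assert f1["firstorder_Mean"] == pytest.approx(
        f0["firstorder_Mean"] + 100.0)


def test_extract_all_rejects_ineligible_mask():
    img, msk = _lesion()
    tiny = np.zeros_like(msk.values)
    tiny[30:32, 30:32] = True  # 4 mm^3 < 30 mm^3
    with pytest.raises(ValueError, match="volume"):
        extract_all(img, BinaryMask(tiny))
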