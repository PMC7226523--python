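import itertools

import numpy as np
import pytest
import pywt

from radsurv import (
    ExtractionConfig,
    ImageVolume,
    extract_all,
    feature_manifest,
    feature_names,
    firstorder_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
    wavelet_decompose,
)
from radsurv.features import (
    CLASS_FEATURES,
    WAVELET_BANDS,
    glrlm_matrix,
    glszm_matrix,
    gldm_matrix,
)

import _oracles as oracles
from conftest import random_roi, roi_from_levels


class TestPanelLayout:
    def test_names_and_counts(self):
        names = feature_names()
        assert len(names) == 841
        assert len(set(names)) == 841
        orig = [n for n in names if n.startswith("original_")]
        wav = [n for n in names if n.startswith("wavelet_")]
        assert len(orig) == 105
        assert len(wav) == 736
        counts = {cls: len(f) for cls, f in CLASS_FEATURES.items()}
        assert counts == {
            "shape": 13, "firstorder": 18, "glcm": 23, "gldm": 14,
            "glrlm": 16, "glszm": 16, "ngtdm": 5,
        }
        # shape only under the original filter
        assert not any("_shape_" in n for n in wav)
        # every band carries the 92 non-shape features
        for band in WAVELET_BANDS:
            assert sum(n.startswith(f"wavelet_{band}_") for n in names) == 92

    def test_manifest_matches_names(self):
        man = feature_manifest()
        assert [m["name"] for m in man] == feature_names()
        assert {m["feature_class"] for m in man} == set(CLASS_FEATURES)


class TestWavelet:
    def test_eight_bands_on_input_grid(self):
        x = np.random.default_rng(0).normal(size=(10, 12, 14))
        bands = wavelet_decompose(x)
        assert list(bands) == ["".join(c) for c in itertools.product("LH", repeat=3)]
        assert all(b.shape == x.shape for b in bands.values())

    def test_constant_volume(self):
        bands = wavelet_decompose(np.full((12, 12, 12), 5.0))
        for name, b in bands.items():
            if "H" in name:
                assert np.abs(b).max() < 1e-8
        # low-pass filter has gain sqrt(2) per axis
        assert np.allclose(bands["LLL"], 5.0 * 2 ** 1.5)

    def test_impulse_matches_brute_force_convolution(self):
        x = np.zeros((8, 8, 8))
        x[3, 4, 2] = 1.0
        wav = pywt.Wavelet("coif1")
        lo, hi = np.array(wav.dec_lo), np.array(wav.dec_hi)
        bands = wavelet_decompose(x, "coif1")
        for label in ("LLL", "HLH", "HHH", "LHL"):
            kernels = [lo if c == "L" else hi for c in label]
            expected = oracles.conv3d_periodic_separable(x, kernels)
            assert np.allclose(bands[label], expected, atol=1e-10), label

    def test_volume_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="filter length"):
            wavelet_decompose(np.zeros((4, 8, 8)))


class TestGLCM:
    def test_hand_enumerated_2x2_plane(self):
        # levels [[1,1],[1,2]] in one slice: per-direction counts enumerable
        roi = roi_from_levels(np.array([[[1], [1]], [[1], [2]]]))
        f = glcm_features(roi)
        # direction contrasts: (1,0,0)->0.5, (0,1,0)->0.5, (1,1,0)->1, (1,-1,0)->0
        assert f["Contrast"] == pytest.approx(0.5)
        assert f["MaximumProbability"] == pytest.approx((0.5 + 0.5 + 0.5 + 1.0) / 4)

    def test_constant_roi_degenerate_values(self):
        roi = roi_from_levels(np.ones((3, 3, 3), int))
        f = glcm_features(roi)
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0  # documented sentinel
        assert f["MCC"] == 1.0
        assert f["JointEntropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["JointEnergy"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            roi = random_roi(rng, shape=(4, 5, 4), n_levels=3)
            ng = roi.n_levels
            f = glcm_features(roi)
            per_dir = []
            for d in oracles.DIRECTIONS_13:
                counts = oracles.glcm_counts(roi.levels, d, ng)
                if counts.sum() == 0:
                    continue
                p = counts / counts.sum()
                i = np.arange(1, ng + 1)
                contrast = sum(
                    p[a, b] * (i[a] - i[b]) ** 2
                    for a in range(ng) for b in range(ng)
                )
                per_dir.append(contrast)
            assert f["Contrast"] == pytest.approx(np.mean(per_dir), rel=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        levels = rng.integers(1, 4, size=(5, 5, 5)).astype(np.int32)
        f0 = glcm_features(roi_from_levels(levels))
        f1 = glcm_features(roi_from_levels(np.rot90(levels, axes=(0, 1)).copy()))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], rel=1e-9), k

    def test_single_voxel_returns_flagged_nan(self):
        levels = np.zeros((3, 3, 3), int)
        levels[1, 1, 1] = 1
        f = glcm_features(roi_from_levels(levels))
        assert all(np.isnan(v) for v in f.values())


class TestRunZoneDependence:
    def test_constant_cube_single_zone(self):
        roi = roi_from_levels(np.ones((3, 3, 3), int))
        mat = glszm_matrix(roi.levels, 1)
        assert mat.shape == (1, 27)
        assert mat[0, 26] == 1  # one zone of size 27
        f = glszm_features(roi)
        assert f["ZonePercentage"] == pytest.approx(1 / 27)

    def test_constant_cube_run_counts_by_hand(self):
        roi = roi_from_levels(np.ones((3, 3, 3), int))
        # axis direction: 9 runs of length 3
        mat = glrlm_matrix(roi.levels, (1, 0, 0), 1)
        assert mat[0, 2] == 9 and mat.sum() == 9
        # plane diagonal: run lengths 3,2,2,1,1 per slice, 3 slices
        mat = glrlm_matrix(roi.levels, (1, 1, 0), 1)
        assert mat[0, 0] == 6 and mat[0, 1] == 6 and mat[0, 2] == 3

    def test_stripes_large_vs_small_area(self):
        levels = np.ones((6, 6, 2), int)
        levels[::2] = 2  # two interleaved large zones
        f = glszm_features(roi_from_levels(levels))
        assert f["LargeAreaEmphasis"] > f["SmallAreaEmphasis"]

    @pytest.mark.parametrize("builder", ["glrlm", "glszm", "gldm"])
    def test_matrices_match_enumeration_oracles(self, builder):
        rng = np.random.default_rng(9)
        for _ in range(6):
            roi = random_roi(rng, shape=(5, 4, 5), n_levels=4)
            ng = roi.n_levels
            if builder == "glrlm":
                for d in [(1, 0, 0), (0, 1, 1), (1, -1, 1)]:
                    mat = glrlm_matrix(roi.levels, d, ng)
                    expected = oracles.glrlm_counts(roi.levels, d, ng)
                    got = {
                        (g + 1, r + 1): mat[g, r]
                        for g in range(mat.shape[0])
                        for r in range(mat.shape[1])
                        if mat[g, r] > 0
                    }
                    assert got == expected
            elif builder == "glszm":
                mat = glszm_matrix(roi.levels, ng)
                expected = oracles.glszm_zones(roi.levels, ng)
                got = {
                    (g + 1, s + 1): mat[g, s]
                    for g in range(mat.shape[0])
                    for s in range(mat.shape[1])
                    if mat[g, s] > 0
                }
                assert got == expected
            else:
                mat = gldm_matrix(roi.levels, ng)
                expected = oracles.gldm_counts(roi.levels, ng)
                got = {
                    (g + 1, j + 1): mat[g, j]
                    for g in range(mat.shape[0])
                    for j in range(mat.shape[1])
                    if mat[g, j] > 0
                }
                assert got == expected

    def test_ngtdm_matches_neighborhood_oracle(self):
        rng = np.random.default_rng(10)
        roi = random_roi(rng, shape=(4, 4, 3), n_levels=3)
        s, n = oracles.ngtdm_s_n(roi.levels, roi.n_levels)
        f = ngtdm_features(roi)
        np_vox = n.sum()
        p = n / np_vox
        coarseness = 1.0 / np.sum(p * s)
        assert f["Coarseness"] == pytest.approx(coarseness, rel=1e-9)

    def test_ngtdm_checkerboard_slab_by_hand(self):
        # 3x3x1 checkerboard of levels 1/2; s_i from manual neighborhood sums
        levels = np.zeros((3, 3, 1), int)
        for i in range(3):
            for j in range(3):
                levels[i, j, 0] = 1 + (i + j) % 2
        s, n = oracles.ngtdm_s_n(levels, 2)
        f = ngtdm_features(roi_from_levels(levels))
        p = n / 9
        assert f["Coarseness"] == pytest.approx(1.0 / (p * s).sum(), rel=1e-9)
        assert n.tolist() == [5, 4]


class TestFirstOrderAndShape:
    def test_constant_roi(self):
        f = firstorder_features(np.full((3, 3, 3), 9.0), np.ones((3, 3, 3), bool))
        assert f["Variance"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Entropy"] == 0.0

    def test_hand_arithmetic(self):
        vol = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        f = firstorder_features(vol, np.ones((4, 1, 1), bool), bin_width=1.0)
        assert f["Mean"] == 2.5
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(7.5))
        assert f["Energy"] == 30.0
        assert f["Range"] == 3.0

    def test_digital_ball_sphericity_and_volume(self):
        shape = (26, 26, 26)
        r_mm = 20.0
        spacing = (2.0, 2.0, 2.0)
        center = (np.asarray(shape) - 1) / 2
        grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
        dist = np.sqrt((((grid - center) * spacing) ** 2).sum(-1))
        mask = dist <= r_mm
        f = shape_features(mask, spacing)
        analytic = 4 / 3 * np.pi * r_mm ** 3
        assert f["MeshVolume"] == pytest.approx(analytic, rel=0.05)
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.05)
        assert f["Maximum3DDiameter"] == pytest.approx(2 * r_mm, rel=0.1)
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)


@pytest.fixture(scope="module")
def phantom():
    rng = np.random.default_rng(12)
    data = 100 + 10 * rng.normal(size=(20, 20, 20))
    center = 9.5
    grid = np.stack(np.meshgrid(*[np.arange(20)] * 3, indexing="ij"), -1)
    mask = (((grid - center) / 6.0) ** 2).sum(-1) <= 1
    vol = ImageVolume(data, (2.0, 2.0, 2.0))
    msk = ImageVolume(mask, (2.0, 2.0, 2.0))
    return vol, msk


class TestExtractAll:
    def test_full_panel_and_determinism(self, phantom):
        vol, msk = phantom
        cfg = ExtractionConfig(resample=False)
        fv1 = extract_all(vol, msk, cfg, patient_id="x")
        fv2 = extract_all(vol, msk, cfg, patient_id="x")
        assert list(fv1.values) == feature_names()
        assert fv1.values == fv2.values

    def test_intensity_shift_behavior(self, phantom):
        vol, msk = phantom
        cfg = ExtractionConfig(resample=False)
        base = extract_all(vol, msk, cfg).values
        shifted_vol = ImageVolume(vol.data + 100.0, vol.spacing_mm, vol.origin)
        shifted = extract_all(shifted_vol, msk, cfg).values
        for name in feature_names():
            if "_shape_" in name:
                assert shifted[name] == pytest.approx(base[name], rel=1e-9)
            elif any(f"_{c}_" in name for c in ("glcm", "gldm", "glrlm", "glszm", "ngtdm")):
                # min-referenced binning: discrete texture is shift invariant
                assert shifted[name] == pytest.approx(base[name], rel=1e-7), name
        assert shifted["original_firstorder_Mean"] == pytest.approx(
            base["original_firstorder_Mean"] + 100.0
        )
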