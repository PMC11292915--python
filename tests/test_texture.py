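"""Texture engine: discretization, matrix builders vs brute force, filters."""

import numpy as np
import pytest

from radsig.imagio import ImageVolume, SegmentationMask
from radsig.texture import (
    DiscretizationSpec,
    FeatureConfig,
    discretize,
    extract_all,
    filter_bank,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    glszm_features,
    ngtdm_features,
    ngtdm_table,
)

from _oracles import (
    auc_bruteforce,  # noqa: F401  (imported for symmetry with other suites)
    glcm_bruteforce,
    glszm_zones_bruteforce,
    ngtdm_bruteforce,
)
from conftest import random_labelled_voi


def as3d(grid2d):
    return np.asarray(grid2d)[None, :, :]


class TestDiscretize:
    def test_fixed_width_formula(self):
        vals = np.array([[[0.0, 10.0, 20.0, 30.0]]])
        lab, ng = discretize(vals, np.ones_like(vals, bool), DiscretizationSpec("width", 10.0))
        np.testing.assert_array_equal(lab[0, 0], [1, 2, 3, 4])
        assert ng == 4

    def test_fixed_width_skips_empty_levels(self):
        vals = np.array([[[0.0, 5.0, 25.0]]])
        lab, _ = discretize(vals, np.ones_like(vals, bool), DiscretizationSpec("width", 10.0))
        np.testing.assert_array_equal(lab[0, 0], [1, 1, 3])

    def test_constant_voi_single_level(self):
        vals = np.full((2, 2, 2), 5.0)
        for spec in (DiscretizationSpec("width", 10.0), DiscretizationSpec("count", bin_count=8)):
            lab, ng = discretize(vals, np.ones_like(vals, bool), spec)
            assert ng == 1
            assert set(np.unique(lab)) == {1}

    def test_fixed_count_covers_range(self, rng):
        vals = rng.normal(size=(4, 4, 4)) * 100
        mask = np.ones_like(vals, bool)
        lab, ng = discretize(vals, mask, DiscretizationSpec("count", bin_count=7))
        assert ng <= 7
        assert lab[mask].min() == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), DiscretizationSpec())


class TestFirstOrder:
    def test_symmetric_skewness_and_even_median(self):
        assert firstorder_features([1.0, 2.0, 3.0])["Skewness"] == pytest.approx(0.0)
        assert firstorder_features([1.0, 2.0, 3.0, 4.0])["Median"] == pytest.approx(2.5)

    def test_skewed_example(self):
        # population moments: m2 = 3, m3 = 6 -> 6 / 3^1.5
        f = firstorder_features([1.0, 1.0, 1.0, 5.0])
        assert f["Skewness"] == pytest.approx(6 / 3**1.5, abs=1e-9)
        assert f["Skewness"] == pytest.approx(1.1547, abs=1e-4)

    def test_kurtosis_of_normal_sample_near_three(self, rng):
        f = firstorder_features(rng.standard_normal(200_000))
        assert f["Kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_zero_variance_policy(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            f = firstorder_features([4.0, 4.0, 4.0])
        assert f["Skewness"] == 0.0
        assert np.isnan(f["Kurtosis"])


class TestGLCM:
    def test_single_direction_hand_example(self):
        lab = as3d([[1, 1], [2, 2]]).astype(np.int32)
        p = glcm_matrix(lab, offsets=((0, 0, 1),))
        np.testing.assert_allclose(p, np.diag([0.5, 0.5]))
        ii, jj = np.meshgrid([1, 2], [1, 2], indexing="ij")
        mu = 1.5
        cp = np.sum((ii + jj - 2 * mu) ** 4 * p)
        assert cp == pytest.approx(1.0)

    def test_constant_voi_prominence_zero(self):
        lab = np.ones((3, 3, 3), dtype=np.int32)
        assert glcm_features(lab)["ClusterProminence"] == pytest.approx(0.0)

    def test_single_voxel_rejected(self):
        lab = np.zeros((3, 3, 3), dtype=np.int32)
        lab[1, 1, 1] = 1
        with pytest.raises(ValueError):
            glcm_features(lab)

    def test_matrix_properties(self, rng):
        for _ in range(5):
            lab = random_labelled_voi(rng)
            p = glcm_matrix(lab)
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, p.T, atol=1e-15)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(5):
            lab = random_labelled_voi(rng, shape=(4, 4, 4))
            np.testing.assert_allclose(glcm_matrix(lab), glcm_bruteforce(lab), atol=1e-12)


class TestGLSZM:
    def test_hand_enumerated_slab(self):
        lab = as3d([[1, 1], [2, 3]]).astype(np.int32)
        f = glszm_features(lab)
        assert f["SmallAreaEmphasis"] == pytest.approx(0.75)
        assert f["SizeZoneNonUniformity"] == pytest.approx(5 / 3)
        assert f["SmallAreaLowGrayLevelEmphasis"] == pytest.approx(0.2037, abs=1e-4)
        assert f["ZoneVariance"] == pytest.approx(0.2222, abs=1e-4)
        assert f["ZonePercentage"] == pytest.approx(0.75)

    def test_constant_voi_single_zone(self):
        lab = np.ones((2, 3, 2), dtype=np.int32)
        n = lab.size
        f = glszm_features(lab)
        assert f["ZonePercentage"] == pytest.approx(1 / n)
        assert f["SmallAreaEmphasis"] == pytest.approx(1 / n**2)

    def test_bounds(self, rng):
        for _ in range(5):
            lab = random_labelled_voi(rng)
            f = glszm_features(lab)
            assert 0 < f["ZonePercentage"] <= 1
            assert 0 < f["SmallAreaEmphasis"] <= 1


class TestNGTDM:
    def test_constant_voi_busyness_zero(self):
        lab = np.ones((3, 3, 3), dtype=np.int32)
        assert ngtdm_features(lab)["Busyness"] == 0.0

    def test_full_neighbourhood_rule_hand_example(self):
        # 2D slab: only the centre voxel has all 8 neighbours; the grid
        # sums to 20, so its neighbour mean is (20 - 2)/8 = 2.25 and
        # s_2 = |2 - 2.25| = 0.25
        lab = np.array([[1, 1, 2], [2, 2, 3], [3, 3, 3]], dtype=np.int32)
        n_i, p_i, s_i = ngtdm_table(lab, require_full_neighbourhood=True)
        assert n_i.tolist() == [0.0, 1.0, 0.0]
        assert s_i[1] == pytest.approx(0.25)
        assert p_i[1] == pytest.approx(1.0)

    def test_matches_neighbour_enumeration_oracle(self, rng):
        for _ in range(5):
            lab = random_labelled_voi(rng, shape=(4, 4, 4), ng=3)
            n_i, p_i, s_i = ngtdm_table(lab)
            bn, bp, bs = ngtdm_bruteforce(lab)
            np.testing.assert_allclose(n_i, bn)
            np.testing.assert_allclose(p_i, bp)
            np.testing.assert_allclose(s_i, bs, atol=1e-9)


class TestFilterBank:
    def _vol(self, data):
        return ImageVolume(np.asarray(data, dtype=float), spacing=(1.0, 1.0, 1.0))

    def test_lowpass_of_constant_is_constant(self):
        vol = self._vol(np.full((8, 8, 8), 10.0))
        lll = filter_bank(vol, ("wavelet",))["wavelet_LLL"]
        assert np.ptp(lll) == pytest.approx(0.0, abs=1e-9)

    def test_log_of_constant_is_zero(self):
        vol = self._vol(np.full((8, 8, 8), 10.0))
        log = filter_bank(vol, ("log_sigma",))["log_sigma_2_0_mm_3D"]
        np.testing.assert_allclose(log, 0.0, atol=1e-9)

    def test_squareroot_map(self):
        vol = self._vol(np.array([[[0.0, 1.0, 4.0]]]))
        np.testing.assert_allclose(
            filter_bank(vol, ("squareroot",))["squareroot"][0, 0], [0.0, 1.0, 2.0]
        )

    def test_unknown_filter_lists_supported(self):
        vol = self._vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="supported"):
            filter_bank(vol, ("wavelet", "sobel"))

    def test_wavelet_yields_eight_subbands(self):
        vol = self._vol(np.random.default_rng(0).normal(size=(6, 6, 6)))
        out = filter_bank(vol, ("wavelet",))
        assert len(out) == 8
        assert {"wavelet_LLL", "wavelet_HHL", "wavelet_HLL", "wavelet_LHL"} <= set(out)
        assert all(v.shape == (6, 6, 6) for v in out.values())


class TestExtractAll:
    def test_canonical_names_present(self, small_cohort):
        row = extract_all(small_cohort.volumes[0], small_cohort.masks_obs1[0])
        assert "exponential_glszm_SmallAreaEmphasis" in row
        assert "wavelet_HLL_glcm_ClusterProminence" in row
        assert "lbp_3D_k_ngtdm_Busyness" in row
        assert "log_sigma_2_0_mm_3D_glszm_ZonePercentage" in row
        assert "squareroot_firstorder_Skewness" in row

    def test_deterministic(self, small_cohort):
        cfg = FeatureConfig(filters=("original", "squareroot"))
        a = extract_all(small_cohort.volumes[1], small_cohort.masks_obs1[1], cfg)
        b = extract_all(small_cohort.volumes[1], small_cohort.masks_obs1[1], cfg)
        assert a == b

    def test_rotation_invariance_of_pooled_features(self, rng):
        data = rng.normal(0.0, 50.0, size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 3:9] = True
        cfg = FeatureConfig(filters=("original",))
        vol = ImageVolume(data, spacing=(1.0, 1.0, 1.0))
        row = extract_all(vol, SegmentationMask(mask), cfg)
        rot_vol = ImageVolume(np.rot90(data, axes=(1, 2)).copy(), spacing=(1.0, 1.0, 1.0))
        rot_mask = SegmentationMask(np.rot90(mask, axes=(1, 2)).copy())
        rot_row = extract_all(rot_vol, rot_mask, cfg)
        for name, val in row.items():
            assert rot_row[name] == pytest.approx(val, abs=1e-9), name
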