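"""Texture matrices and features against exhaustive-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpradiomics.core import Parcellation, VoxelVolume
from mpradiomics.texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    N_TEXTURE_FEATURES,
    QuantizedROI,
    TextureConfig,
    compute_glcm_features,
    compute_glrlm_features,
    compute_glszm_features,
    compute_ngtdm_features,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    global_features,
    ngtdm_arrays,
    quantize,
    roi_feature_vector,
    texture_feature_values,
)
from oracles import glcm_bruteforce, glrlm_bruteforce, glszm_bruteforce, ngtdm_bruteforce


def roi_from_grid(grid):
    """QuantizedROI from a dense level grid (0 = outside)."""
    grid = np.asarray(grid, dtype=np.int64)
    coords = np.argwhere(grid > 0)
    levels = grid[grid > 0]
    return QuantizedROI(levels=levels, coords=coords, Ng=max(2, int(levels.max())))


def random_roi(rng, shape, ng):
    """Random ROI on a small grid: random levels, random in/out mask."""
    grid = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    return np.where(mask, grid, 0)


class TestQuantize:
    def test_forced_binning(self):
        q = quantize([0, 1, 2, 3], [[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]],
                     TextureConfig(Ng=2))
        assert q.levels.tolist() == [1, 1, 2, 2]

    def test_constant_roi_maps_to_level_one(self):
        q = quantize([5.0] * 4, np.zeros((4, 3), dtype=int) + np.arange(4)[:, None] * [0, 0, 1],
                     TextureConfig(Ng=8))
        assert q.levels.tolist() == [1, 1, 1, 1]

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.random(40) * 10
        coords = np.column_stack([np.arange(40), np.zeros(40, int), np.zeros(40, int)])
        cfg = TextureConfig(Ng=6)
        q1 = quantize(x, coords, cfg)
        q2 = quantize(a * x + b, coords, cfg)
        assert q1.levels.tolist() == q2.levels.tolist()


class TestGlobalFeatures:
    def test_constant_roi_zero_variance(self):
        assert global_features([3.0, 3.0, 3.0])["variance"] == 0.0

    def test_population_variance(self):
        assert global_features([1, 2, 3, 4])["variance"] == pytest.approx(1.25)

    def test_moments_match_direct_formulas(self, rng):
        x = rng.random(10) * 7
        out = global_features(x)
        mu = x.mean()
        m2 = np.mean((x - mu) ** 2)
        assert out["variance"] == pytest.approx(m2)
        assert out["skewness"] == pytest.approx(np.mean((x - mu) ** 3) / m2**1.5)
        assert out["kurtosis"] == pytest.approx(np.mean((x - mu) ** 4) / m2**2)


class TestMatrixOracles:
    """Implementation matrices equal exhaustive enumeration on small ROIs."""

    @pytest.mark.parametrize("seed", range(12))
    def test_all_matrices_on_random_rois(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(1, 5, size=3))
        ng = int(rng.integers(2, 5))
        grid = random_roi(rng, shape, ng)
        q = QuantizedROI(levels=grid[grid > 0], coords=np.argwhere(grid > 0), Ng=ng)
        assert np.array_equal(glcm_matrix(q), glcm_bruteforce(grid, ng))
        assert np.array_equal(glrlm_matrix(q), glrlm_bruteforce(grid, ng))
        assert np.array_equal(glszm_matrix(q), glszm_bruteforce(grid, ng))
        s_i, n_i, n_valid = ngtdm_arrays(q)
        s_o, n_o, v_o = ngtdm_bruteforce(grid, ng)
        assert np.allclose(s_i, s_o)
        assert np.array_equal(n_i, n_o)
        assert n_valid == v_o

    @pytest.mark.parametrize("seed", range(6))
    def test_glrlm_voxel_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        grid = random_roi(rng, (4, 4, 4), 3)
        q = roi_from_grid(grid)
        counts = glrlm_matrix(q)
        j = np.arange(1, counts.shape[1] + 1)
        assert (counts * j).sum() == 13 * q.n_voxels

    @pytest.mark.parametrize("seed", range(6))
    def test_glszm_partition_property(self, seed):
        rng = np.random.default_rng(200 + seed)
        grid = random_roi(rng, (4, 4, 4), 4)
        q = roi_from_grid(grid)
        counts = glszm_matrix(q)
        j = np.arange(1, counts.shape[1] + 1)
        assert (counts * j).sum() == q.n_voxels


class TestGLCMFeatures:
    def test_constant_roi(self):
        grid = np.ones((2, 2, 2), dtype=int)
        f = compute_glcm_features(roi_from_grid(grid))
        assert f["contrast"] == 0
        assert f["dissimilarity"] == 0
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(1.0)

    def test_2x2_checker_matches_pair_enumeration(self):
        grid = np.array([[[1], [2]], [[2], [1]]])  # 2x2x1
        q = roi_from_grid(grid)
        counts = glcm_bruteforce(grid, 2)
        p = counts / counts.sum()
        f = compute_glcm_features(q)
        i = np.arange(1, 3)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        assert f["energy"] == pytest.approx((p**2).sum())
        assert f["contrast"] == pytest.approx((((ii - jj) ** 2) * p).sum())
        nz = p > 0
        assert f["entropy"] == pytest.approx(-(p[nz] * np.log2(p[nz])).sum())
        assert f["autocorrelation"] == pytest.approx((ii * jj * p).sum())

    def test_uniform_glcm_entropy(self):
        # line of alternating levels -> co-occurrences spread uniformly over
        # the two off-diagonal cells: entropy = log2(2)
        grid = np.array([[[1, 2, 1, 2]]])
        f = compute_glcm_features(roi_from_grid(grid), TextureConfig(Ng=2))
        assert f["entropy"] == pytest.approx(1.0)


class TestGLRLMFeatures:
    def test_single_line_run(self):
        grid = np.ones((1, 1, 4), dtype=int)
        q = roi_from_grid(grid)
        f = compute_glrlm_features(q, directions=[(0, 0, 1)])
        assert f["SRE"] == pytest.approx(1 / 16)
        assert f["LRE"] == pytest.approx(16)
        assert f["RP"] == pytest.approx(1 / 4)

    def test_alternating_levels_all_unit_runs(self):
        grid = np.array([[[1, 2, 1, 2]]])
        f = compute_glrlm_features(roi_from_grid(grid), directions=[(0, 0, 1)])
        assert f["SRE"] == pytest.approx(1.0)

    def test_random_roi_matches_run_enumeration(self):
        rng = np.random.default_rng(7)
        grid = random_roi(rng, (3, 3, 3), 3)
        q = roi_from_grid(grid)
        counts = glrlm_bruteforce(grid, q.Ng)
        p = counts / counts.sum()
        i = np.arange(1, q.Ng + 1)[:, None]
        j = np.arange(1, counts.shape[1] + 1)[None, :]
        f = compute_glrlm_features(q)
        assert f["SRE"] == pytest.approx((p / j**2).sum())
        assert f["GLN"] == pytest.approx((p.sum(axis=1) ** 2).sum())
        assert f["HGRE"] == pytest.approx((p * i**2).sum())


class TestGLSZMFeatures:
    def test_worked_single_slice_grid(self):
        grid = np.array([[[1, 1, 2], [2, 2, 2], [3, 3, 3]]]).transpose(1, 2, 0)
        q = roi_from_grid(grid)
        counts = glszm_matrix(q)
        # zones: level 1 size 2, level 2 size 4, level 3 size 3
        assert counts[0, 1] == 1 and counts[1, 3] == 1 and counts[2, 2] == 1
        assert counts.sum() == 3
        p = counts / 3
        i = np.arange(1, q.Ng + 1)[:, None]
        j = np.arange(1, counts.shape[1] + 1)[None, :]
        f = compute_glszm_features(q)
        assert f["LZHGE"] == pytest.approx((p * i**2 * j**2).sum())
        assert f["SZLGE"] == pytest.approx((p / (i**2 * j**2)).sum())
        assert f["ZSN"] == pytest.approx((p.sum(axis=0) ** 2).sum())
        assert f["ZP"] == pytest.approx(3 / 9)

    def test_constant_roi_single_zone(self):
        n = 27
        grid = np.ones((3, 3, 3), dtype=int)
        f = compute_glszm_features(roi_from_grid(grid))
        assert f["ZP"] == pytest.approx(1 / n)
        assert f["LZHGE"] == pytest.approx(n**2)


class TestNGTDMFeatures:
    def test_constant_roi_sentinels(self):
        grid = np.ones((2, 2, 2), dtype=int)
        cfg = TextureConfig(coarseness_sentinel=1e6)
        f = compute_ngtdm_features(roi_from_grid(grid), cfg)
        assert f["coarseness"] == 1e6
        assert f["contrast"] == 0.0

    def test_checkerboard_matches_hand_enumeration(self):
        grid = np.array([[[1, 2], [2, 1]]])  # 2x2x1 checkerboard
        q = roi_from_grid(grid)
        s, n, v = ngtdm_arrays(q)
        # each voxel has 3 neighbors: two of the other level, one of its own
        # mean neighbor level differs from own level by 2/3
        assert v == 4
        assert s[0] == pytest.approx(2 * 2 / 3)
        assert s[1] == pytest.approx(2 * 2 / 3)

    def test_flip_invariance(self, rng):
        grid = random_roi(rng, (3, 4, 3), 4)
        q1 = roi_from_grid(grid)
        q2 = roi_from_grid(grid[::-1, :, ::-1])
        f1 = compute_ngtdm_features(q1)
        f2 = compute_ngtdm_features(q2)
        for name in NGTDM_NAMES:
            assert f1[name] == pytest.approx(f2[name])


class TestFeatureVector:
    def _volume_and_parc(self, rng, constant=False):
        data = np.full((6, 6, 6), 10.0) if constant else rng.random((6, 6, 6)) * 50
        vol = VoxelVolume(data, (2, 2, 2), "structural")
        labels = np.zeros((6, 6, 6), dtype=np.int64)
        labels[1:5, 1:5, 1:5] = 1
        parc = Parcellation(labels, {1: "cube"}, "cortical_atlas")
        return vol, parc

    def test_length_43_and_order(self, rng):
        vol, parc = self._volume_and_parc(rng)
        feats = roi_feature_vector(vol, parc, 1)
        assert len(feats) == N_TEXTURE_FEATURES == 43
        families = [fam for fam, _ in feats]
        assert families[:3] == ["global"] * 3
        assert families.count("GLCM") == 9
        assert families.count("GLRLM") == 13
        assert families.count("GLSZM") == 13
        assert families.count("NGTDM") == 5

    def test_constant_roi_known_positions(self, rng):
        vol, parc = self._volume_and_parc(rng, constant=True)
        feats = roi_feature_vector(vol, parc, 1)
        assert feats[("global", "variance")] == 0.0
        assert feats[("GLCM", "contrast")] == 0.0
        assert feats[("GLCM", "homogeneity")] == pytest.approx(1.0)

    def test_deterministic(self, rng):
        vol, parc = self._volume_and_parc(rng)
        f1 = roi_feature_vector(vol, parc, 1)
        f2 = roi_feature_vector(vol, parc, 1)
        assert f1 == f2

    def test_matrix_features_affine_invariant(self, rng):
        x = rng.random(200) * 30 + 5
        coords = np.argwhere(np.ones((5, 5, 8), dtype=bool))
        f1 = texture_feature_values(x, coords)
        f2 = texture_feature_values(3.0 * x + 11.0, coords)
        for fam, name in f1:
            if fam != "global":
                assert f1[(fam, name)] == pytest.approx(f2[(fam, name)]), (fam, name)
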