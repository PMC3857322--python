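"""Second-level t maps, smoothness estimation, Monte-Carlo extent threshold."""

import numpy as np
import pytest
from scipy import ndimage, stats

from reliacase import group as grp

from conftest import make_tiny_dataset


class TestSecondLevelT:
    def test_one_sample_hand_arithmetic(self):
        # betas {1,2,3}: mean 2, sd 1 -> t = 2 sqrt(3), df = 2
        t, df, zero = grp._one_sample(np.array([[1.0], [2.0], [3.0]]))
        assert t[0] == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert df == 2 and not zero[0]

    def test_identical_groups_give_zero_t(self):
        ds = make_tiny_dataset(n_dd=4, n_td=4, dims=(4, 4, 4), sigma_e=0.0, seed=1)
        ds.betas[4:] = ds.betas[:4]  # TD identical to DD
        smap = grp.second_level_t(ds, "comparison", "two_sample",
                                  np.ones((4, 4, 4), bool))
        assert np.allclose(smap.t, 0.0)

    def test_label_swap_negates_t(self):
        ds = make_tiny_dataset(n_dd=4, n_td=4, dims=(4, 4, 4), seed=2)
        mask = np.ones((4, 4, 4), bool)
        smap = grp.second_level_t(ds, "comparison", "two_sample", mask)
        flipped = make_tiny_dataset(n_dd=4, n_td=4, dims=(4, 4, 4), seed=2)
        flipped.betas = np.concatenate([ds.betas[4:], ds.betas[:4]])
        smap2 = grp.second_level_t(flipped, "comparison", "two_sample", mask)
        assert np.allclose(smap.t, -smap2.t)

    def test_zero_variance_voxel_capped_and_flagged(self):
        ds = make_tiny_dataset(n_dd=4, n_td=4, dims=(4, 4, 4), seed=3)
        ds.betas[:, :, :, 0, 0, 0] = 5.0
        smap = grp.second_level_t(ds, "comparison", "one_sample",
                                  np.ones((4, 4, 4), bool), group="DD")
        assert smap.t[0, 0, 0] == grp.T_CAP
        assert smap.qc_zero_variance[0, 0, 0]

    def test_restricted_to_mask(self):
        ds = make_tiny_dataset(n_dd=4, n_td=4, dims=(4, 4, 4), seed=4)
        mask = np.zeros((4, 4, 4), bool)
        mask[0] = True
        smap = grp.second_level_t(ds, "comparison", "two_sample", mask)
        assert np.all(smap.t[~mask] == 0.0)
        with pytest.raises(ValueError, match="empty"):
            grp.second_level_t(ds, "comparison", "two_sample", np.zeros((4, 4, 4), bool))


class TestSmoothness:
    def test_white_noise_floors_at_voxel_size(self):
        rng = np.random.default_rng(0)
        mask = np.ones((16, 16, 16), bool)
        ests = [grp.estimate_smoothness(rng.standard_normal((2, 16, 16, 16)),
                                        mask, (3.0, 3.0, 3.0)) for _ in range(10)]
        mean = np.nanmean(ests, axis=0)
        assert np.all(np.abs(mean - 3.0) / 3.0 < 0.20)

    def test_planted_smoothness_recovered(self):
        rng = np.random.default_rng(1)
        mask = np.ones((24, 24, 24), bool)
        sigma_vox = 7.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        vols = np.stack([ndimage.gaussian_filter(
            rng.standard_normal((40, 40, 40)), sigma_vox)[8:32, 8:32, 8:32]
            for _ in range(6)])
        fwhm = grp.estimate_smoothness(vols, mask, (3.0, 3.0, 3.0))
        assert np.all(np.abs(fwhm - 7.0) < 1.5)

    def test_constant_volume_rejected(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError, match="constant"):
            grp.estimate_smoothness(np.ones((3, 8, 8, 8)), mask, (3.0, 3.0, 3.0))

    def test_thin_axis_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="axis 2"):
            fwhm = grp.estimate_smoothness(rng.standard_normal((3, 12, 12, 1)),
                                           np.ones((12, 12, 1), bool), (3.0, 3.0, 3.0))
        assert np.isnan(fwhm[2]) and np.isfinite(fwhm[0])


def _bfs_max_cluster(binary):
    """Independent 6-connectivity labeling by breadth-first search."""
    visited = np.zeros_like(binary, dtype=bool)
    best = 0
    coords = np.argwhere(binary)
    binset = {tuple(c) for c in coords}
    for start in map(tuple, coords):
        if visited[start]:
            continue
        size = 0
        stack = [start]
        visited[start] = True
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                nb = (x + dx, y + dy, z + dz)
                if nb in binset and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        best = max(best, size)
    return best


class TestMonteCarloExtent:
    def test_alpha_one_means_no_correction(self):
        spec = grp.ClusterThresholdSpec(alpha=1.0, iterations=100, seed=0)
        spec = grp.monte_carlo_cluster_extent(spec, np.ones((8, 8, 8), bool))
        assert spec.kstar == 1

    def test_matches_independent_bernoulli_oracle(self):
        # FWHM 0: suprathreshold voxels are iid Bernoulli; re-simulate with an
        # independent generator and BFS labeling, compare k* within +-1
        mask = np.ones((10, 10, 10), bool)
        iters = 400
        spec = grp.ClusterThresholdSpec(voxel_p=0.01, alpha=0.05, iterations=iters,
                                        fwhm_mm=0.0, seed=5)
        spec = grp.monte_carlo_cluster_extent(spec, mask)
        rng = np.random.default_rng(1234)
        p_half = 0.005  # each sign exceeds with p/2
        maxima = np.empty(iters, dtype=int)
        for i in range(iters):
            pos = rng.random(mask.shape) < p_half
            neg = rng.random(mask.shape) < p_half
            maxima[i] = max(_bfs_max_cluster(pos), _bfs_max_cluster(neg))
        k_oracle = 1
        while (maxima >= k_oracle).mean() > 0.05:
            k_oracle += 1
        assert abs(spec.kstar - k_oracle) <= 1

    def test_kstar_nondecreasing_in_fwhm(self):
        mask = np.ones((14, 14, 14), bool)
        ks = []
        for fwhm in (0.0, 4.0, 8.0):
            spec = grp.ClusterThresholdSpec(iterations=150, fwhm_mm=fwhm, seed=9)
            ks.append(grp.monte_carlo_cluster_extent(spec, mask).kstar)
        assert ks == sorted(ks)

    def test_unstable_tail_warning(self):
        spec = grp.ClusterThresholdSpec(alpha=0.01, iterations=100, seed=0)
        with pytest.warns(UserWarning, match="unstable"):
            grp.monte_carlo_cluster_extent(spec, np.ones((6, 6, 6), bool))


class TestApplyThreshold:
    def _smap_from_t(self, t, voxel_p=0.01, df=15):
        mask = np.ones(t.shape, bool)
        p = 2 * stats.t.sf(np.abs(t), df)
        return grp.StatMap(t=t, df=df, p=p, mask=mask, contrast="test",
                           voxel_p=voxel_p)

    def test_nothing_suprathreshold_empty(self):
        smap = self._smap_from_t(np.zeros((6, 6, 6)))
        out, table = grp.apply_cluster_threshold(smap, kstar=3)
        assert not out.any() and table.empty

    def test_cluster_below_kstar_removed(self):
        t = np.zeros((8, 8, 8))
        t[2:4, 2, 2] = 10.0  # size 2 cluster
        out, table = grp.apply_cluster_threshold(self._smap_from_t(t), kstar=3)
        assert not out.any() and table.empty

    def test_two_blobs_only_large_survives(self):
        t = np.zeros((12, 12, 12))
        t[1, 1, 1:6] = 8.0                      # size 5
        t[5:10, 5:10, 5:7] = -8.0               # size 50, negative direction
        out, table = grp.apply_cluster_threshold(self._smap_from_t(t), kstar=10)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 50
        assert table.iloc[0]["sign"] == -1
        assert (out < 0).sum() == 50 and (out > 0).sum() == 0
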