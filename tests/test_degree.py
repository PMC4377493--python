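import numpy as np
import pandas as pd
import pytest

from connfeed.bold import BoldRun
from connfeed.degree import (DegreeParams, cluster_threshold_mc,
                             degree_change_test, degree_map, find_clusters,
                             roi_significance_ratio, smooth_volume)
from connfeed.grids import VolumeGrid
from connfeed.roi import RoiRegistry, RoiSpec
from connfeed.synthetic import orthonormal_timecourses

from conftest import make_exact_corr_volume


def brute_force_degree(data, threshold, direction):
    """O(V^2) pairwise oracle over all voxel pairs."""
    shape = data.shape[:3]
    voxels = list(np.ndindex(*shape))
    series = np.array([data[v] for v in voxels])
    r = np.corrcoef(series)
    counts = np.zeros(len(voxels), dtype=int)
    for i in range(len(voxels)):
        for j in range(len(voxels)):
            if i == j:
                continue
            hit = r[i, j] < threshold if direction == "less" else r[i, j] > threshold
            counts[i] += hit
    out = np.zeros(shape)
    for idx, v in enumerate(voxels):
        out[v] = counts[idx]
    return out


class TestSmoothing:
    def _run(self, data):
        return BoldRun(data=data, tr_s=2.0, affine=np.diag([2.0, 2.0, 3.0, 1.0]))

    def test_zero_fwhm_identity(self, rng):
        run = self._run(rng.standard_normal((8, 8, 6, 3)))
        out = smooth_volume(run, 0.0)
        np.testing.assert_array_equal(out.data, run.data)

    def test_impulse_matches_sampled_gaussian(self):
        data = np.zeros((15, 15, 11, 1))
        data[7, 7, 5, 0] = 1.0
        fwhm = 4.0
        out = smooth_volume(self._run(data), fwhm).data[..., 0]
        sigma_mm = fwhm / 2.3548200450309493
        voxel = np.array([2.0, 2.0, 3.0])
        ii, jj, kk = np.indices((15, 15, 11))
        d2 = (((ii - 7) * voxel[0]) ** 2 + ((jj - 7) * voxel[1]) ** 2
              + ((kk - 5) * voxel[2]) ** 2)
        kernel = np.exp(-d2 / (2 * sigma_mm**2))
        kernel /= kernel.sum()
        # scipy's separable kernel is the sampled (discretely normalised)
        # Gaussian; compare against that sampling
        sg = sigma_mm / voxel
        axes = [np.exp(-((np.arange(n) - c) ** 2) / (2 * s**2))
                for n, c, s in [(15, 7, sg[0]), (15, 7, sg[1]), (11, 5, sg[2])]]
        expected = (axes[0][:, None, None] * axes[1][None, :, None]
                    * axes[2][None, None, :])
        expected /= expected.sum()
        assert np.abs(out - expected).max() < 1e-6

    def test_interior_impulse_preserves_sum(self):
        data = np.zeros((21, 21, 15, 1))
        data[10, 10, 7, 0] = 1.0
        out = smooth_volume(self._run(data), 5.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_volume(self._run(rng.standard_normal((4, 4, 4, 2))), -1.0)


class TestDegreeMap:
    def test_matches_brute_force_on_random_volume(self, rng):
        data = rng.standard_normal((6, 6, 4, 40))
        for theta, direction in [(-0.25, "less"), (0.3, "greater")]:
            params = DegreeParams(threshold=theta, direction=direction,
                                  block_size=17)
            dm = degree_map(data, params)
            oracle = brute_force_degree(data, theta, direction)
            np.testing.assert_array_equal(dm.counts, oracle)

    def test_block_partition_independence(self, rng):
        data = rng.standard_normal((5, 5, 3, 30))
        maps = [degree_map(data, DegreeParams(block_size=b)).counts
                for b in (1, 7, 75, 1000)]
        for m in maps[1:]:
            np.testing.assert_array_equal(maps[0], m)

    def test_single_pair_crossing_decrements_by_one(self):
        # one voxel pair at r = -0.4 before and +0.3 after the threshold
        shape = (4, 4, 2)
        va, vb = (0, 0, 0), (3, 3, 1)
        pre = make_exact_corr_volume(shape, {(va, vb): -0.4}, seed=0)
        post = make_exact_corr_volume(shape, {(va, vb): 0.3}, seed=0)
        params = DegreeParams(threshold=-0.25, direction="less")
        d_pre = degree_map(pre, params).counts
        d_post = degree_map(post, params).counts
        assert d_pre[va] - d_post[va] == 1
        assert d_pre[vb] - d_post[vb] == 1
        change = d_pre - d_post
        change[va] = change[vb] = 0
        assert np.abs(change).max() == 0

    def test_directional_duality_single_voxel_negation(self, rng):
        # negating one voxel's series flips the sign of its correlations, so
        # its (theta, less) degree becomes its (-theta, greater) degree
        data = rng.standard_normal((4, 4, 3, 25))
        v = (1, 2, 0)
        flipped = data.copy()
        flipped[v] = -flipped[v]
        less = degree_map(data, DegreeParams(threshold=-0.2, direction="less"))
        greater = degree_map(flipped, DegreeParams(threshold=0.2,
                                                   direction="greater"))
        assert less.counts[v] == greater.counts[v]

    def test_direction_complementarity(self, rng):
        # with continuous data and no ties, below + above threshold = V - 1
        data = rng.standard_normal((4, 4, 3, 25))
        less = degree_map(data, DegreeParams(threshold=-0.2, direction="less"))
        greater = degree_map(data, DegreeParams(threshold=-0.2,
                                                direction="greater"))
        np.testing.assert_array_equal(less.counts + greater.counts,
                                      np.full(data.shape[:3], 47.0))

    def test_symmetric_contribution(self, rng):
        # each below-threshold pair adds exactly 1 to both endpoints
        data = rng.standard_normal((4, 4, 2, 30))
        dm = degree_map(data, DegreeParams(threshold=-0.25))
        assert int(np.nansum(dm.counts)) % 2 == 0

    def test_zero_variance_voxels_dropped(self, rng):
        data = rng.standard_normal((3, 3, 2, 20))
        data[0, 0, 0, :] = 7.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            dm = degree_map(data)
        assert not dm.mask[0, 0, 0]
        assert np.isnan(dm.counts[0, 0, 0])

    def test_too_few_timepoints(self, rng):
        with pytest.raises(ValueError, match="time points"):
            degree_map(rng.standard_normal((3, 3, 2, 2)))


class TestPairedT:
    def test_post_equals_pre_gives_zero(self, rng):
        maps = rng.poisson(10.0, size=(4, 5, 5, 3)).astype(float)
        t = degree_change_test(maps, maps.copy())
        np.testing.assert_array_equal(t, np.zeros_like(t[0]) + t * 0)

    def test_hand_computed_single_voxel(self):
        pre = np.array([[[[10.0]]], [[[12.0]]], [[[11.0]]]])
        post = np.array([[[[8.0]]], [[[9.0]]], [[[7.0]]]])
        d = (post - pre).ravel()
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t = degree_change_test(pre, post)
        assert t.ravel()[0] == pytest.approx(t_oracle, abs=1e-12)

    def test_sign_flip_negates(self, rng):
        pre = rng.normal(10, 2, size=(5, 4, 4, 2))
        post = rng.normal(9, 2, size=(5, 4, 4, 2))
        t1 = degree_change_test(pre, post)
        t2 = degree_change_test(post, pre)
        np.testing.assert_allclose(t1, -t2, atol=1e-10)

    def test_needs_two_subjects(self, rng):
        m = rng.normal(size=(1, 3, 3, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            degree_change_test(m, m)


class TestClusters:
    def test_single_voxel_below_min_size(self):
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 10.0
        res = find_clusters(stat, 5.0, min_size=2)
        assert res.n_clusters == 0

    def test_l_shaped_blob_18_connectivity(self):
        stat = np.zeros((6, 6, 3))
        blob = [(1, 1, 1), (2, 1, 1), (3, 1, 1), (3, 2, 1), (3, 3, 1)]
        for v in blob:
            stat[v] = 8.0
        res = find_clusters(stat, 5.0, connectivity=18)
        assert res.n_clusters == 1
        assert res.clusters.iloc[0]["size"] == 5

    def test_diagonal_voxels_join_only_with_wider_connectivity(self):
        stat = np.zeros((4, 4, 4))
        stat[1, 1, 1] = stat[2, 2, 2] = 9.0  # corner neighbours
        assert find_clusters(stat, 5.0, connectivity=18).n_clusters == 2
        assert find_clusters(stat, 5.0, connectivity=26).n_clusters == 1

    def test_entire_mask_single_cluster(self):
        stat = np.full((4, 4, 2), 9.0)
        res = find_clusters(stat, 5.0)
        assert res.n_clusters == 1
        assert res.clusters.iloc[0]["size"] == 32

    def test_direction_less_picks_negative_clusters(self):
        stat = np.zeros((5, 5, 2))
        stat[0:2, 0, 0] = -9.0
        res = find_clusters(stat, -5.0, direction="less")
        assert res.n_clusters == 1
        assert res.clusters.iloc[0]["peak_stat"] == -9.0

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            find_clusters(np.zeros((3, 3, 3)), 1.0, connectivity=10)


class TestMonteCarlo:
    def test_deterministic_given_seed(self):
        mask = np.ones((12, 12, 8), dtype=bool)
        args = dict(voxel_sizes=np.array([3.0, 3.0, 3.5]), fwhm_mm=6.0,
                    voxel_p=0.01, n_iter=150)
        k1 = cluster_threshold_mc(mask, seed=5, **args)
        k2 = cluster_threshold_mc(mask, seed=5, **args)
        assert k1 == k2

    def test_unsmoothed_strict_threshold_small_clusters(self):
        mask = np.ones((10, 10, 6), dtype=bool)
        k = cluster_threshold_mc(mask, np.array([3.0, 3.0, 3.5]), fwhm_mm=0.0,
                                 voxel_p=0.001, n_iter=200, seed=0)
        assert k <= 3

    def test_min_size_nondecreasing_in_fwhm(self):
        mask = np.ones((14, 14, 10), dtype=bool)
        sizes = [cluster_threshold_mc(mask, np.array([3.0, 3.0, 3.5]),
                                      fwhm_mm=f, voxel_p=0.01, n_iter=150, seed=2)
                 for f in (0.0, 6.0, 12.0)]
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_threshold_mc(np.zeros((4, 4, 4), dtype=bool),
                                 np.ones(3), 6.0, n_iter=100)


class TestRoiRatio:
    def _registry(self):
        affine = np.eye(4)
        affine[:3, 3] = -5.0
        grid = VolumeGrid(shape=(11, 11, 11), affine=affine)
        rois = (RoiSpec(name="a", network="MVN", center=(0, 0, 0), radius=2.4),
                RoiSpec(name="b", network="DMN", center=(4, 4, 4), radius=1.4))
        return RoiRegistry(rois=rois, grid=grid)

    def test_all_nonsignificant_zero_percent(self):
        reg = self._registry()
        table = roi_significance_ratio(np.zeros(reg.grid.shape, dtype=bool), reg)
        assert (table["percent"] == 0.0).all()

    def test_fully_significant_roi_100_percent(self):
        reg = self._registry()
        table = roi_significance_ratio(np.ones(reg.grid.shape, dtype=bool), reg)
        assert (table["percent"] == 100.0).all()

    def test_hand_counted_fraction(self):
        reg = self._registry()
        sets = reg.voxel_sets()
        mask = np.zeros(reg.grid.shape, dtype=bool)
        vox_a = sets["a"]
        mask[vox_a[0, 0], vox_a[0, 1], vox_a[0, 2]] = True
        mask[vox_a[1, 0], vox_a[1, 1], vox_a[1, 2]] = True
        table = roi_significance_ratio(mask, reg).set_index("roi")
        assert table.loc["a", "n_significant"] == 2
        assert table.loc["a", "percent"] == pytest.approx(200.0 / len(vox_a))
        assert table.loc["b", "percent"] == 0.0
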