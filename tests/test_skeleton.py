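"""Skeletonization, projection, permutation testing, overlap classes."""

import numpy as np
import pytest

from anisomre import skeleton as sk


class TestMakeSkeleton:
    def test_below_threshold_gives_empty_skeleton(self):
        s = sk.make_skeleton(np.full((12, 12, 12), 0.1))
        assert s.n_voxels == 0

    def test_thick_slab_thins_to_central_sheet(self):
        fa = np.zeros((20, 20, 20))
        fa[:, :, 8:13] = 0.6  # 5 voxels thick
        s = sk.make_skeleton(fa)
        z = np.argwhere(s.mask)[:, 2]
        assert s.n_voxels > 0
        assert len(np.unique(z)) <= 2
        assert set(np.unique(z)) <= {9, 10, 11}

    def test_skeleton_contained_in_thresholded_mask(self, cohort32):
        fa = cohort32.mean_map("fa")
        s = sk.make_skeleton(fa)
        assert np.all(fa[s.mask] > 0.2)

    def test_deterministic(self, cohort32):
        fa = cohort32.mean_map("fa")
        assert np.array_equal(sk.make_skeleton(fa).mask, sk.make_skeleton(fa).mask)

    def test_fa_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="FA"):
            sk.make_skeleton(np.full((8, 8, 8), 1.5))


class TestProjection:
    def _slab_skeleton(self):
        fa = np.zeros((20, 20, 20))
        fa[:, :, 8:13] = 0.6
        return sk.make_skeleton(fa)

    def test_shared_grid_degenerates_to_direct_sampling(self):
        s = self._slab_skeleton()
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(20, 20, 20))
        proj = sk.project_to_skeleton(vol, s.mean_fa, s)
        assert np.allclose(proj, vol[s.mask])

    def test_constant_map_projects_to_constant(self, cohort32):
        fa = cohort32.mean_map("fa")
        s = sk.make_skeleton(fa)
        proj = sk.project_to_skeleton(np.full(fa.shape, 3.5), cohort32.subjects[0].maps["fa"], s)
        assert np.nanmax(np.abs(proj - 3.5)) == 0.0

    def test_shifted_tract_recovered_through_projection(self):
        """Subject whose slab is offset by one voxel along the sheet normal:
        projection still lands on the tract-center value, where naive
        sampling would read the off-center voxel."""
        s = self._slab_skeleton()
        subj_fa = np.zeros((20, 20, 20))
        subj_fa[:, :, 9:14] = 0.6  # shifted +1 in z
        subj_map = np.full((20, 20, 20), -1.0)
        subj_map[:, :, 11] = 7.0  # value at the shifted slab's center (max FA ridge)
        subj_fa[:, :, 11] = 0.8  # center is the subject's FA maximum
        proj = sk.project_to_skeleton(subj_map, subj_fa, s)
        center = np.argwhere(s.mask)[:, 2] == 10
        assert np.all(proj[center] == 7.0)

    def test_masked_out_window_flags_missing(self):
        s = self._slab_skeleton()
        subj_fa = np.zeros((20, 20, 20))  # subject has no white matter at all
        proj = sk.project_to_skeleton(np.ones((20, 20, 20)), subj_fa, s)
        assert np.all(np.isnan(proj))

    def test_grid_mismatch_rejected(self):
        s = self._slab_skeleton()
        with pytest.raises(ValueError, match="grid"):
            sk.project_to_skeleton(np.zeros((10, 10, 10)), np.zeros((10, 10, 10)), s)


class TestVoxelwiseGroupTest:
    def test_type_one_error_calibrated(self):
        """Random labels on i.i.d. Gaussian data: ~5% of voxels significant
        (pooled over 20 replicate runs)."""
        rng = np.random.default_rng(11)
        fracs = []
        for rep in range(20):
            x = rng.normal(size=(38, 400))
            labels = ["young"] * 20 + ["old"] * 18
            s = sk.voxelwise_group_test(x, labels, n_perm=500, seed=rep)
            fracs.append(np.mean(s.p_two <= 0.05))
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_saturated_power_limit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(38, 200))
        x[:20] += 10.0  # 10 pooled SDs
        labels = ["young"] * 20 + ["old"] * 18
        s = sk.voxelwise_group_test(x, labels, n_perm=500, seed=0)
        assert np.mean(s.significant("greater")) >= 0.99

    def test_permutation_agrees_with_parametric_t(self):
        """Permutation p within 0.02 of the analytic t distribution p for
        Gaussian data at n_perm = 5000."""
        from scipy import stats

        rng = np.random.default_rng(5)
        x = rng.normal(size=(38, 60))
        x[:20, :30] += 0.8
        labels = ["young"] * 20 + ["old"] * 18
        s = sk.voxelwise_group_test(x, labels, n_perm=5000, seed=1)
        p_param = 2 * stats.t.sf(np.abs(s.t_stat), df=36)
        assert np.max(np.abs(s.p_two - p_param)) < 0.02

    def test_null_p_values_superuniform(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        x = rng.normal(size=(38, 500))
        labels = ["young"] * 20 + ["old"] * 18
        s = sk.voxelwise_group_test(x, labels, n_perm=5000, seed=2)
        ks = stats.kstest(s.p_two, "uniform")
        assert ks.statistic < 0.05 or ks.pvalue > 0.01

    def test_zero_variance_voxel_p_one(self):
        x = np.random.default_rng(0).normal(size=(10, 5))
        x[:, 2] = 4.2  # flat voxel
        labels = ["a"] * 5 + ["b"] * 5
        s = sk.voxelwise_group_test(x, labels, n_perm=200, seed=0)
        assert s.p_two[2] == 1.0 and s.n_zero_variance == 1

    def test_low_coverage_voxels_dropped(self):
        x = np.random.default_rng(0).normal(size=(10, 4))
        x[:5, 1] = np.nan  # 50% coverage
        labels = ["a"] * 5 + ["b"] * 5
        s = sk.voxelwise_group_test(x, labels, n_perm=200, seed=0)
        assert np.isnan(s.p_two[1]) and s.dropped_voxels == 1

    def test_small_n_perm_warns(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        with pytest.warns(UserWarning, match="n_perm"):
            sk.voxelwise_group_test(x, ["a"] * 4 + ["b"] * 4, n_perm=50, seed=0)

    def test_single_group_rejected(self):
        x = np.zeros((4, 3))
        with pytest.raises(ValueError, match="2 groups"):
            sk.voxelwise_group_test(x, ["a"] * 4, n_perm=100, seed=0)


class TestPercentSignificantAndOverlap:
    def _stat(self, p):
        n = len(p)
        return sk.StatMap(
            t_stat=np.zeros(n), p_greater=np.asarray(p), p_less=np.ones(n),
            p_two=np.asarray(p), alpha=0.05, n_perm=100, seed=0, contrast=("a", "b"),
        )

    def test_extremes_and_half(self):
        assert sk.percent_significant(self._stat([0.01] * 10)) == 100.0
        assert sk.percent_significant(self._stat([0.5] * 10)) == 0.0
        assert sk.percent_significant(self._stat([0.01] * 5 + [0.5] * 5)) == 50.0

    def test_overlap_partition(self):
        rng = np.random.default_rng(0)
        a = rng.random(100) < 0.3
        b = rng.random(100) < 0.4
        ov = sk.overlap_classes(a, b)
        assert sum(ov.counts.values()) == 100
        assert ov.counts["both"] == int(np.sum(a & b))

    def test_disjoint_and_identical_masks(self):
        a = np.array([True] * 5 + [False] * 5)
        assert sk.overlap_classes(a, ~a).counts["both"] == 0
        ov = sk.overlap_classes(a, a)
        assert ov.counts["both"] == 5
        assert ov.counts["mre_only"] == 0 and ov.counts["dti_only"] == 0


class TestEffectSizeMonotonicity:
    def test_percent_significant_grows_with_effect(self):
        """3-point effect-size sweep: larger group separation never reduces
        the significant fraction (sign test over replicates)."""
        rng = np.random.default_rng(21)
        labels = ["young"] * 20 + ["old"] * 18
        wins = 0
        for rep in range(5):
            fracs = []
            noise = rng.normal(size=(38, 300))
            for effect in (0.0, 0.5, 1.0):
                x = noise.copy()
                x[:20] += effect
                s = sk.voxelwise_group_test(x, labels, n_perm=300, seed=rep)
                fracs.append(np.mean(s.significant("greater")))
            wins += int(fracs[0] <= fracs[1] <= fracs[2])
        assert wins >= 4
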