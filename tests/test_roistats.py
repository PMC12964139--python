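"""Tract-ROI summaries, t-tests, Bonferroni, added-value logistic model."""

import numpy as np
import pytest

from anisomre import roistats as rs
from anisomre.phantom import LABELS, TRACT_NAMES
from anisomre.skeleton import make_skeleton


@pytest.fixture(scope="module")
def skeleton32(cohort32):
    return make_skeleton(cohort32.mean_map("fa"))


class TestRoiSkeletonMeans:
    def test_constant_map(self, atlas32, skeleton32):
        means, counts = rs.roi_skeleton_means(np.full(atlas32.shape, 2.5), atlas32, skeleton32)
        for t in TRACT_NAMES:
            assert counts[t] > 0
            assert means[t] == pytest.approx(2.5)

    def test_off_skeleton_voxels_ignored(self, atlas32, skeleton32):
        vol = np.full(atlas32.shape, -9.0)  # off-skeleton value
        vol[skeleton32.mask] = 4.0
        means, _ = rs.roi_skeleton_means(vol, atlas32, skeleton32)
        for t in TRACT_NAMES:
            assert means[t] == pytest.approx(4.0)

    def test_brute_force_enumeration(self, atlas32, skeleton32):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=atlas32.shape)
        means, counts = rs.roi_skeleton_means(vol, atlas32, skeleton32)
        t = "CST"
        sel = (atlas32.labels == LABELS[t]) & skeleton32.mask
        acc = 0.0
        n = 0
        for idx in np.argwhere(sel):
            acc += vol[tuple(idx)]
            n += 1
        assert n == counts[t]
        assert means[t] == pytest.approx(acc / n, abs=1e-12)

    def test_grid_mismatch_rejected(self, atlas32, skeleton32):
        with pytest.raises(ValueError, match="grid"):
            rs.roi_skeleton_means(np.zeros((8, 8, 8)), atlas32, skeleton32)


class TestGroupTtest:
    def test_identical_groups_null(self):
        v = [1.0, 2.0, 3.0, 4.0]
        r = rs.group_ttest(v, v)
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 1, 18)
        r1, r2 = rs.group_ttest(a, b), rs.group_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.df == 36

    def test_matches_permutation_oracle(self):
        """Pooled-t p within 0.02 of a 10,000-shuffle permutation p."""
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.7, 1.0, 18)
        r = rs.group_ttest(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            pa, pb = pooled[:20], pooled[20:]
            sp = np.sqrt(((19 * pa.var(ddof=1)) + (17 * pb.var(ddof=1))) / 36)
            t = (pa.mean() - pb.mean()) / (sp * np.sqrt(1 / 20 + 1 / 18))
            count += abs(t) >= abs(r.t)
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p_perm - r.p) < 0.02

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            rs.group_ttest([1.0], [1.0, 2.0])


class TestTtestFromSummary:
    def test_fmin_stiffness_crosses_bonferroni_bound(self):
        """Pooled t-test from the young/old forceps-minor stiffness
        summaries (2.94 +/- 0.23, n=20 vs 2.61 +/- 0.23, n=18) lands
        below 0.001."""
        r = rs.ttest_from_summary(
            rs.GroupSummary(2.94, 0.23, 20), rs.GroupSummary(2.61, 0.23, 18)
        )
        assert r.df == 36
        assert r.p < 0.001

    def test_equal_means_p_one(self):
        r = rs.ttest_from_summary(rs.GroupSummary(2.5, 0.3, 10), rs.GroupSummary(2.5, 0.3, 12))
        assert r.p == pytest.approx(1.0)

    def test_agrees_with_raw_data_to_machine_precision(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.4, 1.3, 18)
        r_raw = rs.group_ttest(a, b)
        r_sum = rs.ttest_from_summary(
            rs.GroupSummary(a.mean(), a.std(ddof=1), 20),
            rs.GroupSummary(b.mean(), b.std(ddof=1), 18),
        )
        assert r_sum.t == pytest.approx(r_raw.t, abs=1e-12)
        assert r_sum.p == pytest.approx(r_raw.p, abs=1e-12)

    def test_summary_invariants(self):
        with pytest.raises(ValueError):
            rs.GroupSummary(1.0, -0.1, 10)
        with pytest.raises(ValueError):
            rs.GroupSummary(1.0, 0.1, 1)
        with pytest.raises(ValueError):
            rs.GroupSummary(5.0, 0.1, 10, minimum=6.0, maximum=7.0)


class TestBonferroni:
    def test_eight_tract_threshold(self):
        flags, thr = rs.bonferroni([0.005, 0.00625, 0.01], alpha=0.05, k=8)
        assert thr == pytest.approx(0.00625)
        # strict inequality: p exactly at the threshold is not significant
        assert list(flags) == [True, False, False]

    def test_k_one_is_uncorrected(self):
        _, thr = rs.bonferroni([0.04], alpha=0.05, k=1)
        assert thr == 0.05

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rs.bonferroni([0.01], k=0)


class TestAddedValueLogistic:
    LABELS = np.array(["young"] * 20 + ["old"] * 18)

    def test_informative_added_covariate_detected(self):
        rng = np.random.default_rng(0)
        y = (self.LABELS == "old").astype(float)
        base = rng.normal(0, 1, 38)
        added = rng.normal(0, 0.5, 38) + y * 1.5
        res = rs.added_value_logistic(base, added, self.LABELS)
        assert res.converged and not res.separation
        assert res.p < 0.01
        assert res.beta > 0

    def test_beta_reported_on_raw_scale(self):
        rng = np.random.default_rng(1)
        y = (self.LABELS == "old").astype(float)
        base = rng.normal(0, 1, 38)
        added = rng.normal(0, 1, 38) + y
        r1 = rs.added_value_logistic(base, added, self.LABELS)
        r2 = rs.added_value_logistic(base, added * 10.0, self.LABELS)
        assert r2.beta == pytest.approx(r1.beta / 10.0, rel=1e-6)
        assert r2.p == pytest.approx(r1.p, rel=1e-6)

    def test_perfect_separation_flagged(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 38)
        added = np.where(self.LABELS == "old", 10.0, -10.0) + rng.normal(0, 0.01, 38)
        res = rs.added_value_logistic(base, added, self.LABELS)
        assert res.separation
        assert np.isnan(res.p)

    def test_collinear_covariates_flagged(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 38)
        res = rs.added_value_logistic(base, 2.0 * base + 1.0, self.LABELS)
        assert res.collinear
        assert np.isnan(res.p)

    def test_one_group_only_rejected(self):
        with pytest.raises(ValueError, match="group"):
            rs.added_value_logistic(np.zeros(5), np.zeros(5), ["old"] * 5)

    def test_power_monotone_in_conditional_effect(self):
        """Detection rate of the added term rises across a 3-point effect
        sweep (sign test across effect levels)."""
        labels = self.LABELS
        y = (labels == "old").astype(float)
        rates = []
        for effect in (0.0, 0.8, 1.6):
            hits = 0
            for rep in range(60):
                rng = np.random.default_rng(1000 * rep + int(10 * effect))
                base = rng.normal(0, 1, 38) + 0.5 * y
                added = rng.normal(0, 1, 38) + effect * y
                res = rs.added_value_logistic(base, added, labels)
                if res.converged and not res.separation and res.p < 0.05:
                    hits += 1
            rates.append(hits / 60)
        assert rates[0] < rates[1] < rates[2]
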