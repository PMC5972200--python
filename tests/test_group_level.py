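import numpy as np
import pytest
from scipy import stats

from stopsig.cohort import sample_coupled_activation
from stopsig.group_level import (ClusterConfig, bh_fdr, interaction_scan,
                                 label_clusters, posthoc_pearson,
                                 voxelwise_group_model)


def _bh_oracle(p, q):
    """Explicit step-up enumeration, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = 0.0
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * q / m:
            thresh = p[order[k - 1]]
            break
    return p <= thresh if thresh > 0 else np.zeros(m, dtype=bool)


class TestVoxelwiseModel:
    def test_null_two_sample_calibration(self, rng):
        maps = rng.standard_normal((40, 2000))
        group = np.array(["patient"] * 20 + ["control"] * 20)
        age = rng.uniform(20, 45, 40)
        res = voxelwise_group_model(maps, group=group, age=age,
                                    mode="two_sample")
        frac = np.mean(res.p < 0.05)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_difference_power(self, rng):
        """Cohen's d = 1.5 at 10% of voxels passes p<0.001 nearly always
        (noncentral-t power ~ 0.99 at n = 30+38)."""
        n_c, n_p, v = 30, 38, 2000
        maps = rng.standard_normal((n_c + n_p, v))
        planted = np.arange(0, v, 10)
        maps[n_c:, planted] += 1.5
        group = np.array(["control"] * n_c + ["patient"] * n_p)
        age = rng.uniform(20, 45, n_c + n_p)
        res = voxelwise_group_model(maps, group=group, age=age,
                                    mode="two_sample")
        assert np.mean(res.p[planted] < 0.001) >= 0.80

    def test_age_confound_removed(self, rng):
        """With an age effect but no group effect, group p values stay
        uniform once age is covaried."""
        n = 60
        age = np.concatenate([rng.uniform(20, 30, 30), rng.uniform(35, 45, 30)])
        group = np.array(["control"] * 30 + ["patient"] * 30)
        maps = 0.1 * (age[:, None] - age.mean()) + rng.standard_normal((n, 1500))
        res = voxelwise_group_model(maps, group=group, age=age,
                                    mode="two_sample")
        ks = stats.kstest(res.p.ravel(), "uniform")
        assert ks.pvalue > 0.01

    def test_one_sample_detects_mean(self, rng):
        maps = 0.8 + rng.standard_normal((30, 500))
        res = voxelwise_group_model(maps, age=rng.uniform(20, 40, 30),
                                    mode="one_sample")
        assert np.mean(bh_fdr(res.p, 0.05)) > 0.9

    def test_insufficient_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            voxelwise_group_model(rng.standard_normal((4, 10)),
                                  group=np.array(["patient"] * 2 + ["control"] * 2),
                                  mode="two_sample")


class TestBHFDR:
    def test_stepup_example(self):
        rej = bh_fdr([0.001, 0.01, 0.02, 0.03, 0.5], q=0.05)
        assert rej.tolist() == [True, True, True, True, False]

    def test_all_ones_no_rejection(self):
        assert not bh_fdr(np.ones(10), q=0.05).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert bh_fdr([0.04], q=0.05).all()
        assert not bh_fdr([0.06], q=0.05).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(500):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            q = float(rng.uniform(0.01, 0.2))
            assert np.array_equal(bh_fdr(p, q), _bh_oracle(p, q))

    def test_rejections_monotone_in_q(self, rng):
        p = rng.uniform(size=200)
        r1 = bh_fdr(p, 0.02)
        r2 = bh_fdr(p, 0.10)
        assert np.all(r2[r1])  # q1 < q2 -> rejections nested


class TestClusters:
    def test_26_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # diagonal neighbour -> same cluster
        mask[3, 3, 3] = True
        labels, n = label_clusters(mask)
        assert n == 2


class TestInteractionScan:
    def _inputs(self, seed, r_ctrl, r_pat, v=200):
        rng = np.random.default_rng(seed)
        n_c, n_p = 30, 38
        ssrt = np.concatenate([rng.normal(270, 33, n_c), rng.normal(278, 33, n_p)])
        group = np.array(["control"] * n_c + ["patient"] * n_p)
        age = np.concatenate([rng.uniform(24, 37, n_c), rng.uniform(21, 45, n_p)])
        act = np.empty(n_c + n_p)
        act[:n_c] = sample_coupled_activation(ssrt[:n_c], r_ctrl, seed=seed + 1)
        act[n_c:] = sample_coupled_activation(ssrt[n_c:], r_pat, seed=seed + 2)
        maps = 0.5 * rng.standard_normal((n_c + n_p,) + (5, 5, 8))
        maps += act[:, None, None, None]
        return maps, ssrt, group, age

    def test_no_interaction_null_calibration(self):
        maps, ssrt, group, age = self._inputs(3, 0.3, 0.3)
        stat, _ = interaction_scan(maps, ssrt, group, age,
                                   ClusterConfig(n_perm=20, seed=0))
        assert np.nanmean(stat.p < 0.05) == pytest.approx(0.05, abs=0.06)

    def test_group_specific_coupling_detected_voxelwise(self):
        maps, ssrt, group, age = self._inputs(11, -0.8, 0.3)
        stat, _ = interaction_scan(maps, ssrt, group, age,
                                   ClusterConfig(n_perm=50, seed=1))
        assert np.nanmin(stat.p) < 0.001

    def test_zero_variance_voxel_flagged(self):
        maps, ssrt, group, age = self._inputs(5, -0.5, 0.1)
        maps[:, 0, 0, 0] = 7.0  # constant activation
        stat, _ = interaction_scan(maps, ssrt, group, age,
                                   ClusterConfig(n_perm=10, seed=2))
        assert not stat.valid[0, 0, 0]
        assert np.isnan(stat.t[0, 0, 0])

    def test_age_affine_invariance(self):
        maps, ssrt, group, age = self._inputs(7, -0.6, 0.1)
        cfg = ClusterConfig(n_perm=5, seed=3)
        t1, _ = interaction_scan(maps, ssrt, group, age, cfg)
        t2, _ = interaction_scan(maps, ssrt, group, 3.0 * age + 11.0, cfg)
        assert np.allclose(np.nan_to_num(t1.t), np.nan_to_num(t2.t), atol=1e-8)

    def test_misaligned_inputs_rejected(self):
        maps, ssrt, group, age = self._inputs(9, -0.5, 0.1)
        with pytest.raises(ValueError):
            interaction_scan(maps, ssrt[:-1], group, age)


class TestPosthocPearson:
    def test_exact_mode_reproduces_printed_couplings(self):
        rng = np.random.default_rng(0)
        ssrt_c = rng.normal(270, 33, 30)
        ssrt_p = rng.normal(278, 33, 38)
        act_c = sample_coupled_activation(ssrt_c, -0.537, seed=1, exact=True)
        act_p = sample_coupled_activation(ssrt_p, 0.089, seed=2, exact=True)
        out = posthoc_pearson(np.concatenate([act_c, act_p]),
                              np.concatenate([ssrt_c, ssrt_p]),
                              np.array(["control"] * 30 + ["patient"] * 38))
        assert out["control"][0] == pytest.approx(-0.537, abs=1e-10)
        assert out["patient"][0] == pytest.approx(0.089, abs=1e-10)

    def test_perfect_linear_relation(self):
        x = np.arange(5.0)
        out = posthoc_pearson(x, x, np.array(["g"] * 5))
        assert out["g"][0] == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            posthoc_pearson(np.ones(6), np.arange(6.0), np.array(["g"] * 6))
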