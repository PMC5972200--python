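import numpy as np
import pytest

from stopsig.connectivity import (ConfoundAmplitudes, RestRun, default_masks,
                                  denoise, group_fc_difference, motion_qc,
                                  regress_confounds, seed_fc_map,
                                  simulate_rest_run)
from stopsig.first_level import AcquisitionSpec
from stopsig.group_level import ClusterConfig

SPEC = AcquisitionSpec(rest_volumes=210, grid_shape=(6, 6, 6))
NO_CONF = ConfoundAmplitudes(motion=0.0, csf=0.0, wm=0.0)


def _bare_run(data, tr_s=2.0):
    T = data.shape[-1]
    return RestRun(data=data, motion=np.zeros((T, 6)), csf=np.zeros(T),
                   wm=np.zeros(T), outlier_flags=np.zeros(T, dtype=bool),
                   tr_s=tr_s)


class TestMotionQC:
    def _run_with_motion(self, motion):
        T = motion.shape[0]
        return RestRun(data=np.zeros((2, 2, 2, T)), motion=motion,
                       csf=np.zeros(T), wm=np.zeros(T),
                       outlier_flags=np.zeros(T, dtype=bool), tr_s=2.0)

    def test_excess_translation_fails(self):
        m = np.zeros((10, 6))
        m[4, 1] = 1.2
        assert not motion_qc(self._run_with_motion(m))

    def test_excess_rotation_fails(self):
        m = np.zeros((10, 6))
        m[2, 5] = -1.3
        assert not motion_qc(self._run_with_motion(m))

    def test_still_subject_passes(self):
        assert motion_qc(self._run_with_motion(np.zeros((10, 6))))

    def test_boundary_exactly_one_passes(self):
        m = np.zeros((10, 6))
        m[3, 0] = 1.0
        m[7, 4] = -1.0
        assert motion_qc(self._run_with_motion(m))  # strict "more than"


class TestDenoise:
    def test_drops_initial_volumes(self):
        run = simulate_rest_run(SPEC, 0.5, NO_CONF, seed=0)
        assert run.data.shape[-1] == 210
        assert denoise(run).shape[-1] == 206

    def test_too_short_run_rejected(self):
        run = _bare_run(np.random.default_rng(0).standard_normal((2, 2, 2, 20)))
        with pytest.raises(ValueError):
            denoise(run)

    @pytest.mark.parametrize("freq,check", [
        (0.15, lambda ratio: ratio <= 0.10),   # outside the 0.01-0.1 Hz band
        (0.05, lambda ratio: ratio >= 0.80),   # inside the band
    ])
    def test_bandpass_frequency_response(self, freq, check):
        t = np.arange(210) * 2.0
        wave = np.sin(2 * np.pi * freq * t)
        rng = np.random.default_rng(1)
        data = np.tile(wave, (3, 3, 3, 1)) + 1e-6 * rng.standard_normal((3, 3, 3, 210))
        cleaned = denoise(_bare_run(data))
        ratio = cleaned[1, 1, 1].var() / wave[4:].var()
        assert check(ratio)

    def test_confound_regression_recovers_planted_coupling(self):
        """Strong nuisance signals bias the raw correlation; denoising
        restores the planted in-band coupling."""
        seed_mask, target_mask = default_masks(SPEC.grid_shape)
        strong = ConfoundAmplitudes(motion=2.0, csf=2.0, wm=2.0)
        vals = []
        for i in range(15):
            run = simulate_rest_run(SPEC, 0.6, strong, seed=100 + i,
                                    seed_mask=seed_mask, target_mask=target_mask)
            fc = seed_fc_map(denoise(run), seed_mask)
            vals.append(fc.r[target_mask].mean())
        assert np.mean(vals) == pytest.approx(0.6, abs=0.1)

    def test_confound_regression_orthogonal_and_idempotent(self):
        """Residuals are orthogonal to the confound matrix, so applying the
        regression a second time changes nothing."""
        run = simulate_rest_run(SPEC, 0.4, seed=7)
        Y, C = regress_confounds(run)
        assert np.abs(C.T @ Y).max() < 1e-8 * np.abs(Y).max() * len(Y)
        beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
        assert np.allclose(Y - C @ beta, Y, atol=1e-10)

    def test_outlier_volumes_scrubbed(self):
        run = simulate_rest_run(SPEC, 0.5, NO_CONF, seed=3,
                                outlier_volumes=np.array([50, 120]))
        cleaned = denoise(run)
        spikes = np.abs(cleaned[..., [46, 116]])
        assert spikes.max() < np.abs(cleaned).max() * 1.5  # no residual spikes


class TestSeedFC:
    def test_determinism(self):
        a = simulate_rest_run(SPEC, 0.5, seed=5)
        b = simulate_rest_run(SPEC, 0.5, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError):
            simulate_rest_run(SPEC, 1.0)

    def test_voxel_identical_to_seed(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 3, 3, 100))
        seed_mask = np.zeros((3, 3, 3), dtype=bool)
        seed_mask[0, 0, 0] = True
        fc = seed_fc_map(data, seed_mask)
        assert fc.r[0, 0, 0] == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(fc.z[0, 0, 0])  # clipped before atanh

    def test_fisher_z_spot_value(self):
        """Series built with empirical r = 0.5 must map to atanh(0.5)."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        e = rng.standard_normal(200)
        e = e - e.mean() - (e - e.mean()) @ ((x - x.mean()) / x.std()) / 200 * ((x - x.mean()) / x.std())
        y = 0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * (e / e.std())
        data = np.stack([x, y]).reshape(2, 1, 1, 200)
        seed_mask = np.array([[[True]], [[False]]])
        fc = seed_fc_map(data, seed_mask)
        assert fc.z[1, 0, 0] == pytest.approx(0.5493, abs=1e-4)

    def test_zero_variance_voxel_masked(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((2, 2, 2, 50))
        data[1, 1, 1] = 0.0
        seed_mask = np.zeros((2, 2, 2), dtype=bool)
        seed_mask[0, 0, 0] = True
        fc = seed_fc_map(data, seed_mask)
        assert not fc.valid[1, 1, 1]
        assert np.isnan(fc.z[1, 1, 1])

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            seed_fc_map(np.zeros((2, 2, 2, 30)), np.zeros((2, 2, 2), dtype=bool))

    def test_fisher_z_odd_and_monotone(self):
        r = np.linspace(-0.95, 0.95, 39)
        z = np.arctanh(r)
        assert np.allclose(z, -z[::-1])
        assert np.all(np.diff(z) > 0)

    def test_bandpass_preserves_inband_coupling(self):
        seed_mask, target_mask = default_masks(SPEC.grid_shape)
        diffs = []
        for i in range(10):
            run = simulate_rest_run(SPEC, 0.6, NO_CONF, seed=300 + i,
                                    seed_mask=seed_mask, target_mask=target_mask)
            raw = seed_fc_map(run.data[..., 4:], seed_mask)
            filt = seed_fc_map(denoise(run), seed_mask)
            diffs.append(filt.r[target_mask].mean() - raw.r[target_mask].mean())
        assert abs(np.mean(diffs)) < 0.05


class TestGroupFC:
    def test_planted_group_difference_recovered(self):
        spec = AcquisitionSpec(rest_volumes=210, grid_shape=(8, 8, 8))
        seed_mask, target_mask = default_masks(spec.grid_shape)
        rng = np.random.default_rng(0)
        groups = np.array(["control"] * 12 + ["patient"] * 14)
        age = rng.uniform(21, 45, 26)
        z = np.empty((26,) + spec.grid_shape)
        for j, g in enumerate(groups):
            r = 0.6 if g == "control" else 0.3
            run = simulate_rest_run(spec, r, seed=j, seed_mask=seed_mask,
                                    target_mask=target_mask)
            z[j] = seed_fc_map(denoise(run), seed_mask).z
        stat, thr = group_fc_difference(z, groups, age,
                                        ClusterConfig(n_perm=60, seed=1))
        assert thr.mask[target_mask].any()

    def test_single_group_rejected(self, rng):
        z = rng.standard_normal((10, 4, 4, 4))
        with pytest.raises(ValueError):
            group_fc_difference(z, np.array(["patient"] * 10),
                                rng.uniform(20, 40, 10))
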