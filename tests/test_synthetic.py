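"""Synthetic cohort generator: covariance structure, marginals, coupling."""

import numpy as np
import pytest

import nbacknet as nb
from nbacknet.network import BANDS, CONDITIONS
from nbacknet.synthetic import simulate_behavior


def flat_config(**kw):
    """Config without the spatial kernel, for block-structure checks."""
    base = dict(n_subjects=1, spatial_weight=0.0, seed=1)
    base.update(kw)
    return nb.CohortConfig(**base)


class TestConditionCovariance:
    def test_no_planted_effect_gives_identical_cells(self):
        config = nb.CohortConfig(n_subjects=1, delta_integration=0.0,
                                 delta_segregation=0.0, subject_sd=0.0,
                                 seed=1)
        mats = [nb.build_condition_covariance(config, band, condition)
                for band in BANDS for condition in CONDITIONS]
        for m in mats[1:]:
            np.testing.assert_array_equal(m, mats[0])

    def test_two_module_block_structure(self):
        config = flat_config(n_rois=4, n_modules=2, rho_within=0.5,
                             rho_between=0.2, delta_integration=0.0,
                             delta_segregation=0.0, subject_sd=0.0)
        corr = nb.build_condition_covariance(config, "theta", "0back")
        expected = np.array([
            [1.0, 0.5, 0.2, 0.2],
            [0.5, 1.0, 0.2, 0.2],
            [0.2, 0.2, 1.0, 0.5],
            [0.2, 0.2, 0.5, 1.0],
        ])
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_theta_contrast_is_constant_off_block(self):
        config = flat_config(n_rois=8, n_modules=2, subject_sd=0.0)
        base = nb.build_condition_covariance(config, "theta", "0back")
        load = nb.build_condition_covariance(config, "theta", "2back")
        diff = load - base
        module = np.repeat([0, 1], 4)
        same = module[:, None] == module[None, :]
        np.testing.assert_allclose(diff[same], 0.0, atol=1e-12)
        np.testing.assert_allclose(diff[~same], config.delta_integration,
                                   atol=1e-12)

    def test_all_default_cells_are_psd(self):
        config = nb.CohortConfig(n_subjects=1, seed=1)
        for band in BANDS:
            for condition in CONDITIONS:
                for effect in (-0.09, 0.0, 0.09):
                    corr = nb.build_condition_covariance(config, band,
                                                         condition, effect)
                    assert np.linalg.eigvalsh(corr)[0] > -1e-10

    def test_unknown_labels_rejected(self):
        config = nb.CohortConfig(n_subjects=1, seed=1)
        with pytest.raises(ValueError, match="band"):
            nb.build_condition_covariance(config, "gamma-band", "0back")
        with pytest.raises(ValueError, match="condition"):
            nb.build_condition_covariance(config, "theta", "3back")


class TestSimulatePowerMatrix:
    def test_independent_rois_have_small_sample_correlation(self):
        rng = np.random.default_rng(0)
        psm = nb.simulate_power_matrix(np.eye(12), 4000, 0.0, 0.4, rng)
        r = np.corrcoef(psm.values)
        off = r[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(4000)

    def test_zero_log_sd_is_deterministic_level(self):
        rng = np.random.default_rng(0)
        psm = nb.simulate_power_matrix(np.eye(4), 10, 1.5, 0.0, rng)
        np.testing.assert_allclose(psm.values, np.exp(1.5))

    def test_lognormal_attenuation_matches_monte_carlo_oracle(self):
        # oracle: large-sample Pearson r of exp(mu + sd z) pairs with
        # latent rho = 0.9, from 10^6 independent draws
        rho, sd = 0.9, 0.3
        rng = np.random.default_rng(99)
        z1 = rng.standard_normal(1_000_000)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(1_000_000)
        oracle_r = np.corrcoef(np.exp(sd * z1), np.exp(sd * z2))[0, 1]
        corr = np.array([[1.0, rho], [rho, 1.0]])
        psm = nb.simulate_power_matrix(corr, 10_000, 2.0, sd,
                                       np.random.default_rng(3))
        sample_r = np.corrcoef(psm.values)[0, 1]
        assert sample_r == pytest.approx(oracle_r, abs=0.03)

    def test_power_strictly_positive(self):
        rng = np.random.default_rng(1)
        psm = nb.simulate_power_matrix(np.eye(6), 50, 0.0, 1.0, rng)
        assert np.all(psm.values > 0)


class TestSimulateBehavior:
    @staticmethod
    def summaries(l0=0.4, l2=0.35, c0=0.2, c2=0.18):
        return {"0back": {"lambda_theta_int": l0, "c_alpha_int": c0},
                "2back": {"lambda_theta_int": l2, "c_alpha_int": c2}}

    def test_deterministic_limit_recovers_linear_model(self):
        config = nb.BehaviorCouplingConfig(
            rt_intercept=500.0, rt_condition_offset=80.0,
            coef_lambda_theta=0.0, coef_c_alpha=0.0, rt_noise_sd=1e-12,
            rt_nontarget_offset=0.0,
        )
        out = simulate_behavior(self.summaries(), config,
                                np.random.default_rng(0))
        assert out["0back"]["rt_target_ms"] == pytest.approx(500.0, abs=1e-6)
        assert out["2back"]["rt_target_ms"] == pytest.approx(580.0, abs=1e-6)

    def test_reaction_time_floor(self):
        config = nb.BehaviorCouplingConfig(rt_intercept=100.0,
                                           rt_noise_sd=1e-12)
        out = simulate_behavior(self.summaries(), config,
                                np.random.default_rng(0))
        assert out["0back"]["rt_target_ms"] >= 150.0

    def test_accuracy_drop_matches_sampling_oracle(self):
        config = nb.BehaviorCouplingConfig(acc_condition_drop=0.12,
                                           acc_noise_sd=0.02)
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(400):
            out = simulate_behavior(self.summaries(), config, rng)
            diffs.append(out["0back"]["acc_target"]
                         - out["2back"]["acc_target"])
        assert np.mean(diffs) == pytest.approx(0.12, abs=0.01)

    def test_negative_path_length_coupling_produces_negative_correlation(self):
        config = nb.BehaviorCouplingConfig(coef_lambda_theta=-300.0,
                                           rt_noise_sd=5.0,
                                           rt_condition_offset=0.0)
        rng = np.random.default_rng(11)
        negative = 0
        for _ in range(100):
            lams, rts = [], []
            for s in range(10):
                l0, l2 = 0.40 + 0.05 * rng.standard_normal(2)
                out = simulate_behavior(self.summaries(l0=l0, l2=l2),
                                        config, rng)
                lams += [l0, l2]
                rts += [out["0back"]["rt_target_ms"],
                        out["2back"]["rt_target_ms"]]
            if np.corrcoef(lams, rts)[0, 1] < 0:
                negative += 1
        assert negative >= 95


class TestGenerateCohort:
    def test_deterministic_regeneration(self):
        config = nb.CohortConfig(n_subjects=2, n_rois=40, seed=5)
        a = nb.generate_cohort(config)
        b = nb.generate_cohort(config)
        for sa, sb in zip(a.subjects, b.subjects):
            for key in sa.power:
                np.testing.assert_array_equal(sa.power[key].values,
                                              sb.power[key].values)
            assert sa.behavior == sb.behavior

    def test_adding_subjects_does_not_perturb_existing_ones(self):
        small = nb.generate_cohort(
            nb.CohortConfig(n_subjects=2, n_rois=40, seed=5)
        )
        large = nb.generate_cohort(
            nb.CohortConfig(n_subjects=3, n_rois=40, seed=5)
        )
        for sa, sb in zip(small.subjects, large.subjects[:2]):
            for key in sa.power:
                np.testing.assert_array_equal(sa.power[key].values,
                                              sb.power[key].values)

    def test_trial_counts_match_study_conditions(self):
        config = nb.CohortConfig(n_subjects=28, n_rois=16, n_modules=8,
                                 seed=2, simulate_behavior_data=False)
        cohort = nb.generate_cohort(config)
        n0 = [s.n_trials["0back"] for s in cohort.subjects]
        n2 = [s.n_trials["2back"] for s in cohort.subjects]
        assert np.mean(n0) == pytest.approx(42.30, abs=1.0)
        assert np.mean(n2) == pytest.approx(36.95, abs=2.0)
        assert min(n0 + n2) >= 10

    def test_trial_count_shared_across_bands(self, tiny_cohort):
        for sub in tiny_cohort.subjects:
            for condition in CONDITIONS:
                trials = {sub.power[(condition, band)].n_trials
                          for band in BANDS}
                assert len(trials) == 1

    def test_power_positive_and_complete(self, tiny_cohort):
        for sub in tiny_cohort.subjects:
            assert set(sub.power) == {(c, b) for c in CONDITIONS
                                      for b in BANDS}
            for psm in sub.power.values():
                assert np.all(psm.values > 0)

    def test_small_cohort_runs_quickly(self):
        import time

        start = time.time()
        cohort = nb.generate_cohort(
            nb.CohortConfig(n_subjects=2, n_rois=8, n_modules=2, seed=9)
        )
        assert time.time() - start < 5.0
        assert cohort.n_subjects == 2

    def test_directory_round_trip(self, tiny_cohort, tmp_path):
        root = tiny_cohort.to_directory(tmp_path / "cohort")
        back = nb.SyntheticCohort.from_directory(root)
        assert back.config.to_dict() == tiny_cohort.config.to_dict()
        for sa, sb in zip(tiny_cohort.subjects, back.subjects):
            for key in sa.power:
                np.testing.assert_allclose(sa.power[key].values,
                                           sb.power[key].values)
            for condition in CONDITIONS:
                ra = sa.behavior[condition]
                rb = sb.behavior[condition]
                for field in ra:
                    assert ra[field] == pytest.approx(rb[field])


class TestConfigValidation:
    def test_rho_ordering_enforced(self):
        with pytest.raises(ValueError, match="rho_within > rho_between"):
            nb.CohortConfig(rho_within=0.2, rho_between=0.4)

    def test_module_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            nb.CohortConfig(n_rois=10, n_modules=3)

    def test_delta_margin_enforced(self):
        with pytest.raises(ValueError, match="delta"):
            nb.CohortConfig(rho_within=0.45, rho_between=0.35,
                            delta_integration=0.2)
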