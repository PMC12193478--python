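"""Synthetic walking-trial and cohort generators."""

import math

import numpy as np
import pytest
from scipy import stats

from gaitvar import (
    CohortSimConfig,
    ConfigError,
    WalkSimConfig,
    expected_duration_correlation,
    noise_sd_for_correlation,
    simulate_cohort,
    simulate_walk_trial,
    subject_features,
    write_keypoint_json,
)
from gaitvar.synthetic import (
    block_exchangeable_correlation,
    features_with_exact_correlation,
    rank2_features,
)


class TestWalkSimConfig:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_frames": 1}, "n_frames"),
            ({"step_sd": -1.0}, "step_sd"),
            ({"dropout_rate": 1.0}, "dropout_rate"),
            ({"dropout_rate": -0.1}, "dropout_rate"),
            ({"lr_asymmetry": -0.5}, "lr_asymmetry"),
            ({"cycle_period": 0.0}, "cycle_period"),
        ],
    )
    def test_invalid_config_names_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            WalkSimConfig(**kwargs).validate()


class TestSimulateWalkTrial:
    def test_zero_noise_trial_has_exactly_zero_displacement_variance(self):
        cfg = WalkSimConfig(n_frames=80, step_mean=10.0, step_sd=0.0,
                            trend=0.0, dropout_rate=0.0, seed=4)
        t1 = simulate_walk_trial(cfg, subject_id="s", trial_id="t1")
        t2 = simulate_walk_trial(WalkSimConfig(n_frames=80, step_mean=10.0,
                                               step_sd=0.0, seed=5),
                                 subject_id="s", trial_id="t2")
        row = subject_features("s", t1, t2)
        assert row["var_mean"] == 0.0
        assert row["var15_t1"] == 0.0 and row["var16_t2"] == 0.0

    def test_same_seed_gives_byte_identical_json(self, tmp_path):
        cfg = WalkSimConfig(n_frames=60, step_sd=2.5, dropout_rate=0.1, seed=9)
        p1 = write_keypoint_json(simulate_walk_trial(cfg), tmp_path / "a.json")
        p2 = write_keypoint_json(simulate_walk_trial(cfg), tmp_path / "b.json")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_walk_trial(WalkSimConfig(seed=1))
        b = simulate_walk_trial(WalkSimConfig(seed=2))
        assert not np.array_equal(a.keypoints, b.keypoints)

    def test_pipeline_variance_matches_monte_carlo_oracle(self):
        """The recovered displacement variance matches a direct re-simulation
        of the generative step rule (clipped-at-zero Gaussian increments)."""
        cfg = WalkSimConfig(n_frames=5000, step_mean=10.0, step_sd=2.0,
                            trend=0.0, dropout_rate=0.0, seed=21)
        seq = simulate_walk_trial(cfg)
        row = subject_features("s", seq, simulate_walk_trial(
            WalkSimConfig(n_frames=5000, step_mean=10.0, step_sd=2.0, seed=22)))
        oracle_rng = np.random.default_rng(777)
        oracle_steps = np.clip(
            cfg.step_mean + oracle_rng.normal(0.0, cfg.step_sd, 200_000), 0.0, None
        )
        oracle_var = oracle_steps.var(ddof=1)
        assert row["var15_t1"] == pytest.approx(oracle_var, rel=0.10)
        assert row["var_mean"] == pytest.approx(oracle_var, rel=0.10)

    def test_lr_asymmetry_scales_right_foot_variance(self):
        cfg = WalkSimConfig(n_frames=4000, step_mean=10.0, step_sd=2.0,
                            lr_asymmetry=2.0, seed=31)
        seq = simulate_walk_trial(cfg)
        row = subject_features("s", seq, simulate_walk_trial(
            WalkSimConfig(n_frames=4000, step_mean=10.0, step_sd=2.0,
                          lr_asymmetry=2.0, seed=32)))
        # right-foot step SD is doubled -> variance ~4x the left foot's
        assert row["var16_t1"] / row["var15_t1"] == pytest.approx(4.0, rel=0.2)

    def test_dropout_rate_lowers_foot_confidences(self):
        seq = simulate_walk_trial(WalkSimConfig(n_frames=2000, dropout_rate=0.2,
                                                seed=41))
        frac_low = float((seq.keypoints[:, 15, 2] < 0.3).mean())
        assert frac_low == pytest.approx(0.2, abs=0.04)


class TestSimulateCohort:
    def test_requires_at_least_two_subjects(self):
        with pytest.raises(ConfigError, match="n_subjects"):
            simulate_cohort(CohortSimConfig(n_subjects=1))

    def test_seed_determinism(self):
        cfg = CohortSimConfig(n_subjects=4, n_frames=100, seed=6)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert a.cohort.equals(b.cohort)
        assert a.trials["S001"][0] == b.trials["S001"][0]

    def test_duration_is_the_sum_of_trial_durations(self):
        sim = simulate_cohort(CohortSimConfig(n_subjects=6, n_frames=100, seed=2))
        np.testing.assert_allclose(
            sim.cohort["duration"],
            sim.cohort["duration1"] + sim.cohort["duration2"],
        )

    def test_noiseless_negative_coupling_gives_exact_minus_one(self):
        sim = simulate_cohort(
            CohortSimConfig(n_subjects=12, n_frames=150, coupling_beta=-0.3,
                            noise_sd=0.0, seed=8)
        )
        merged = sim.cohort.merge(sim.features, on="subject_id")
        r = stats.pearsonr(merged["var_mean"], merged["duration"]).statistic
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_coupling_gives_near_zero_correlation(self):
        n = 400
        sim = simulate_cohort(
            CohortSimConfig(n_subjects=n, n_frames=80, coupling_beta=0.0,
                            noise_sd=1.0, seed=13)
        )
        merged = sim.cohort.merge(sim.features, on="subject_id")
        r = stats.pearsonr(merged["var_mean"], merged["duration"]).statistic
        assert abs(r) < 2.0 / math.sqrt(n)

    def test_calibrated_coupling_recovers_analytic_correlation(self):
        """With noise_sd chosen from the closed form for rho = -0.9 the
        empirical var_mean-duration correlation lands within +/-0.05."""
        beta, rho = -0.3, -0.9
        pilot = simulate_cohort(
            CohortSimConfig(n_subjects=300, n_frames=150, coupling_beta=beta,
                            noise_sd=0.0, seed=99)
        )
        sigma_vm = float(pilot.features["var_mean"].std(ddof=1))
        noise = noise_sd_for_correlation(beta, sigma_vm, rho)
        assert expected_duration_correlation(beta, sigma_vm, noise) == pytest.approx(rho)
        sim = simulate_cohort(
            CohortSimConfig(n_subjects=200, n_frames=150, coupling_beta=beta,
                            noise_sd=noise, seed=100)
        )
        merged = sim.cohort.merge(sim.features, on="subject_id")
        r = stats.pearsonr(merged["var_mean"], merged["duration"]).statistic
        assert r == pytest.approx(rho, abs=0.05)

    def test_scores_span_the_ordinal_scale(self):
        sim = simulate_cohort(CohortSimConfig(n_subjects=60, n_frames=120, seed=17))
        scores = set(sim.cohort["score2_1"]) | set(sim.cohort["score2_2"])
        assert len(scores) >= 3
        assert scores <= {0, 1, 2, 3, 4}

    def test_trial_one_is_slower_on_average(self):
        sim = simulate_cohort(CohortSimConfig(n_subjects=40, n_frames=100, seed=19))
        diff = (sim.cohort["duration1"] - sim.cohort["duration2"]).mean()
        assert diff == pytest.approx(1.5, abs=0.4)


class TestStructuredFeatureGenerators:
    def test_exact_correlation_construction(self):
        R = block_exchangeable_correlation(0.6, 0.2)
        F = features_with_exact_correlation(R, n_subjects=19, seed=5)
        emp = np.corrcoef(F.drop(columns="subject_id").to_numpy().T)
        assert np.abs(emp - R).max() < 1e-10

    def test_rank2_features_have_rank_two(self):
        F = rank2_features(20, seed=3).drop(columns="subject_id").to_numpy()
        centred = F - F.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        assert s[1] > 1e-8 and s[2] < 1e-10
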