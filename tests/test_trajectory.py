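import json
import shutil
import subprocess

import numpy as np
import pytest

from gazetask.trajectory import (
    DEFAULT_GENERATING_EFFECTS,
    ModelSpec,
    fit_trajectory,
    predict_trajectory,
    simulate_trajectory_data,
)


@pytest.fixture(scope="module")
def lognormal_fit_and_truth():
    df = simulate_trajectory_data(n_subjects=150, n_trials=15, seed=31)
    fit = fit_trajectory(df, ModelSpec(family="lognormal", nsteps=2000, burn=800), seed=31)
    return fit, DEFAULT_GENERATING_EFFECTS


@pytest.fixture(scope="module")
def bernoulli_fit_and_truth():
    effects = {
        "intercept": 0.2,
        "age_z": 0.68,
        "mode_remote": 1.10,
        "symmetric_position": -1.59,
        "trial_z": -0.02,
    }
    df = simulate_trajectory_data(
        n_subjects=90,
        n_trials=15,
        family="bernoulli_logit",
        effects=effects,
        re_sds=(0.8, 0.5, 0.1),
        seed=32,
    )
    fit = fit_trajectory(df, ModelSpec(family="bernoulli_logit", nsteps=900, burn=300), seed=32)
    return fit, effects


class TestLognormalTrajectory:
    def test_age_effect_recovered(self, lognormal_fit_and_truth):
        fit, truth = lognormal_fit_and_truth
        age = fit["age_z"]
        assert age.covers(truth["age_z"])
        assert abs(age.mean - truth["age_z"]) < 0.1

    def test_difficulty_gradient_recovered(self, lognormal_fit_and_truth):
        fit, truth = lognormal_fit_and_truth
        sym = fit["symmetric_position"]
        assert sym.mean > 0  # lateral targets are harder (more imprecise)

    def test_convergence_diagnostics_reported(self, lognormal_fit_and_truth):
        fit, _ = lognormal_fit_and_truth
        assert 0.05 < fit.fit.acceptance_fraction < 0.9
        assert all(s.rhat < 1.2 for s in fit.summaries.values())

    def test_null_simulation_covers_zero(self):
        effects = dict.fromkeys(DEFAULT_GENERATING_EFFECTS, 0.0)
        df = simulate_trajectory_data(
            n_subjects=60, n_trials=10, effects=effects, re_sds=(0.3, 0.2, 0.05), seed=33
        )
        fit = fit_trajectory(df, ModelSpec(family="lognormal", nsteps=1200, burn=400), seed=33)
        for name in ("age_z", "mode_remote", "symmetric_position", "trial_z"):
            assert fit[name].covers(0.0), name

    def test_negative_outcomes_rejected(self):
        df = simulate_trajectory_data(n_subjects=25, n_trials=6, seed=34)
        df.loc[df.index[0], "performance"] = -1.0
        with pytest.raises(ValueError):
            fit_trajectory(df, ModelSpec(family="lognormal"))

    def test_small_samples_rejected(self):
        df = simulate_trajectory_data(n_subjects=10, n_trials=6, seed=35)
        with pytest.raises(ValueError):
            fit_trajectory(df)


class TestBernoulliTrajectory:
    def test_centrality_advantage_sign_recovered(self, bernoulli_fit_and_truth):
        """Accuracy falls for lateral targets: the symmetric-position
        coefficient must come back negative."""
        fit, _ = bernoulli_fit_and_truth
        sym = fit["symmetric_position"]
        assert sym.mean < 0
        assert sym.cri_high < 0

    def test_age_effect_positive(self, bernoulli_fit_and_truth):
        fit, _ = bernoulli_fit_and_truth
        assert fit["age_z"].mean > 0

    def test_non_binary_outcomes_rejected(self):
        df = simulate_trajectory_data(n_subjects=25, n_trials=6, seed=36)  # lognormal data
        with pytest.raises(ValueError):
            fit_trajectory(df, ModelSpec(family="bernoulli_logit"))


class TestPredictTrajectory:
    def test_negative_age_coefficient_gives_decreasing_imprecision(self, lognormal_fit_and_truth):
        fit, _ = lognormal_fit_and_truth
        pred = predict_trajectory(fit, np.arange(36, 72, 3))
        assert np.all(np.diff(pred["mean"]) < 0)
        assert (pred["cri_low"] <= pred["mean"]).all()
        assert (pred["mean"] <= pred["cri_high"]).all()

    def test_positive_age_coefficient_gives_increasing_accuracy(self, bernoulli_fit_and_truth):
        fit, _ = bernoulli_fit_and_truth
        pred = predict_trajectory(fit, np.arange(36, 72, 3))
        assert np.all(np.diff(pred["mean"]) > 0)
        assert pred["mean"].between(0, 1).all()

    def test_predictions_bracket_age_bin_means(self, lognormal_fit_and_truth):
        """Posterior predictions at observed ages track the empirical
        age-group medians of a well-specified simulation."""
        fit, _ = lognormal_fit_and_truth
        df = simulate_trajectory_data(n_subjects=150, n_trials=15, seed=31)
        df["age_year"] = df["age_months"] // 12
        emp = np.log(df.groupby("age_year")["performance"].median())
        ages = (df.groupby("age_year")["age_months"].mean()).to_numpy()
        pred = predict_trajectory(fit, ages, mode="remote")
        pred_in = predict_trajectory(fit, ages, mode="in_person")
        # empirical medians (mixed modes) should fall between the two
        # mode-specific predictions, within log-scale slack
        lo = np.minimum(np.log(pred["mean"]), np.log(pred_in["mean"])) - 0.35
        hi = np.maximum(np.log(pred["mean"]), np.log(pred_in["mean"])) + 0.35
        assert np.all(emp.to_numpy() >= lo) and np.all(emp.to_numpy() <= hi)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLme4:
    def test_fixed_effects_match_lmer(self, tmp_path):
        """Independent cross-check: REML estimates from lme4 on the same
        simulated data agree with the posterior means."""
        df = simulate_trajectory_data(n_subjects=120, n_trials=15, seed=40)
        fit = fit_trajectory(df, ModelSpec(family="lognormal", nsteps=2000, burn=800), seed=40)
        data = df.copy()
        data["log_perf"] = np.log(data["performance"])
        data["mode_remote"] = (data["mode"] == "remote").astype(int)
        csv = tmp_path / "traj.csv"
        data.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(log_perf ~ age_z + mode_remote + symmetric_position + trial_z +
                  (1 + symmetric_position + trial_z | subject_id), data = d, REML = TRUE)
        cat(jsonlite::toJSON(as.list(fixef(m)), auto_unbox=TRUE))
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout.strip().splitlines()[-1])
        pairs = {
            "(Intercept)": "intercept",
            "age_z": "age_z",
            "mode_remote": "mode_remote",
            "symmetric_position": "symmetric_position",
            "trial_z": "trial_z",
        }
        for rname, pname in pairs.items():
            assert fit[pname].mean == pytest.approx(ref[rname], abs=0.05), pname
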