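import numpy as np
import pandas as pd
import pytest

from gazetask import (
    SessionConfig,
    SplitPlan,
    fixed_retest_sequence,
    hierarchical_retest,
    simulate_retest_data,
    spearman_brown,
    split_half_coefficient,
    split_trials,
)
from gazetask import test_retest_pearson as retest_pearson


def gaussian_true_score_cohort(n_subjects, n_trials, tau, sigma, seed=0, mean=1.0):
    """True-score model: subject means N(mean, tau^2), trials add N(0, sigma^2).

    Under an odd/even split of n trials the expected half-score correlation
    is the intraclass correlation tau^2 / (tau^2 + sigma^2 / (n/2)).
    """
    rng = np.random.default_rng(seed)
    mu = mean + tau * rng.standard_normal(n_subjects)
    y = mu[:, None] + sigma * rng.standard_normal((n_subjects, n_trials))
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"s{i}" for i in range(n_subjects)], n_trials),
            "trial_index": np.tile(np.arange(n_trials), n_subjects),
            "performance": y.ravel(),
        }
    )


class TestSplitTrials:
    def test_odd_even_sizes(self, rng):
        (a, b), = split_trials(list(range(15)), SplitPlan(method="odd_even"), rng=rng)
        assert (len(a), len(b)) == (8, 7)

    def test_first_second_takes_leading_half(self, rng):
        (a, b), = split_trials(list(range(15)), SplitPlan(method="first_second"), rng=rng)
        assert list(a) == list(range(8)) and list(b) == list(range(8, 15))

    def test_permutated_is_a_partition(self, rng):
        plan = SplitPlan(method="permutated", n_replicates=20)
        for a, b in split_trials(list(range(15)), plan, rng=rng):
            assert set(a) | set(b) == set(range(15))
            assert set(a) & set(b) == set()

    def test_monte_carlo_draws_with_replacement(self):
        plan = SplitPlan(method="monte_carlo", n_replicates=200)
        seen_duplicate = False
        for a, b in split_trials(list(range(15)), plan):
            assert len(a) == len(b) == 7
            if len(set(a)) < len(a) or len(set(b)) < len(b):
                seen_duplicate = True
        assert seen_duplicate

    def test_stratified_split_covers_every_stratum(self, rng):
        """On the adult fixed sequence (3 trials per bin), a stratified
        odd-even split puts every bin into both halves."""
        cfg = SessionConfig(version="hedge", cohort="adult", mode="fixed_retest", seed=1)
        trials = [t for t in fixed_retest_sequence(cfg) if t.phase == "test"]
        bins = [t.bin for t in trials]
        plan = SplitPlan(method="odd_even", stratify=True)
        (a, b), = split_trials(trials, plan, rng=rng, strata=bins)
        assert {bins[i] for i in a} == set(range(10))
        assert {bins[i] for i in b} == set(range(10))

    def test_single_sample_methods_admit_one_replicate(self):
        with pytest.raises(ValueError):
            SplitPlan(method="odd_even", n_replicates=10)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            split_trials([1], SplitPlan(method="odd_even"))


class TestSplitHalfCoefficient:
    def test_identical_halves_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 10))
        df = pd.DataFrame(
            {
                "subject_id": np.repeat([f"s{i}" for i in range(30)], 20),
                "trial_index": np.tile(np.arange(20), 30),
                # second half duplicates the first half exactly
                "performance": np.concatenate([np.tile(v, 2) for v in values]),
            }
        )
        res = split_half_coefficient(df, SplitPlan(method="first_second"))
        assert res.coefficient == pytest.approx(1.0, abs=1e-12)

    def test_constant_scores_are_degenerate(self):
        df = gaussian_true_score_cohort(10, 8, tau=0.0, sigma=0.0, seed=2)
        with pytest.raises(ValueError):
            split_half_coefficient(df, SplitPlan(method="odd_even"))

    def test_matches_analytic_icc(self):
        """Odd-even r against the intraclass correlation oracle
        tau^2/(tau^2 + sigma^2/(n/2))."""
        tau, sigma, n_trials, n_subjects = 0.5, 1.0, 30, 200
        df = gaussian_true_score_cohort(n_subjects, n_trials, tau, sigma, seed=3)
        res = split_half_coefficient(df, SplitPlan(method="odd_even"))
        expected = tau**2 / (tau**2 + sigma**2 / (n_trials / 2))
        tol = 4.0 * (1.0 - expected**2) / np.sqrt(n_subjects)  # ~4 SE of r
        assert res.coefficient == pytest.approx(expected, abs=tol)
        assert res.ci_low < expected < res.ci_high

    def test_resampling_methods_agree_with_single_sample_on_average(self):
        df = gaussian_true_score_cohort(120, 20, tau=0.5, sigma=0.8, seed=4)
        r_oe = split_half_coefficient(df, SplitPlan(method="odd_even")).coefficient
        r_perm = split_half_coefficient(
            df, SplitPlan(method="permutated", n_replicates=300)
        ).coefficient
        assert r_perm == pytest.approx(r_oe, abs=0.1)

    def test_replicate_mean_stabilizes(self):
        df = gaussian_true_score_cohort(80, 16, tau=0.5, sigma=0.8, seed=5)
        r1 = split_half_coefficient(df, SplitPlan(method="permutated", n_replicates=500)).coefficient
        r2 = split_half_coefficient(df, SplitPlan(method="permutated", n_replicates=1000)).coefficient
        assert abs(r1 - r2) < 0.01

    def test_reliability_grows_with_trial_count(self):
        rs = []
        for n_trials in (6, 40):
            df = gaussian_true_score_cohort(300, n_trials, tau=0.4, sigma=1.0, seed=6)
            rs.append(split_half_coefficient(df, SplitPlan(method="odd_even")).coefficient)
        assert rs[1] > rs[0]

    def test_stratified_variant_runs_on_simulated_sessions(self):
        from gazetask import PopulationConfig, analysis_trials, score_responses, simulate_cohort
        records = simulate_cohort(
            PopulationConfig(n_subjects=40, seed=8),
            SessionConfig(version="hedge", mode="fixed_retest", seed=8),
        )
        scored = score_responses(analysis_trials(records))
        res = split_half_coefficient(scored, SplitPlan(method="odd_even", stratify=True))
        assert -1.0 <= res.coefficient <= 1.0


class TestSpearmanBrown:
    def test_identity_at_one(self):
        assert spearman_brown(1.0) == 1.0

    def test_correction_exceeds_raw_for_positive_r(self):
        for r in np.linspace(0.05, 0.95, 10):
            assert spearman_brown(r) >= r

    def test_monotone(self):
        rs = np.linspace(-0.5, 0.99, 50)
        corrected = [spearman_brown(r) for r in rs]
        assert all(a < b for a, b in zip(corrected, corrected[1:]))

    def test_corrected_result_wraps_bounds(self):
        df = gaussian_true_score_cohort(100, 20, tau=0.5, sigma=0.8, seed=7)
        res = split_half_coefficient(df, SplitPlan(method="odd_even"))
        cor = res.corrected_result()
        assert cor.corrected and cor.coefficient == pytest.approx(spearman_brown(res.coefficient))


class TestTestRetestPearson:
    def test_identical_days_give_unit_correlation(self):
        x = np.linspace(0, 1, 50)
        res = retest_pearson(x, x)
        assert res.coefficient == pytest.approx(1.0)

    def test_independent_days_give_near_zero(self):
        rng = np.random.default_rng(0)
        res = retest_pearson(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(res.coefficient) < 0.1
        assert res.ci_low < 0 < res.ci_high

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            retest_pearson([1, 2, 3], [1, 2])


class TestHierarchicalRetest:
    def test_null_correlation_recovered(self):
        df = simulate_retest_data(n_subjects=80, n_trials=10, rho=0.0, seed=21)
        fit = hierarchical_retest(df, family="lognormal", seed=1, nsteps=1200, burn=400)
        rho = fit["rho"]
        assert rho.cri_low < 0.0 < rho.cri_high

    def test_bernoulli_family_recovers_high_correlation(self):
        df = simulate_retest_data(
            n_subjects=100, n_trials=15, rho=0.9, tau=(1.2, 1.2),
            beta_intercept=0.0, family="bernoulli_logit", seed=22,
        )
        fit = hierarchical_retest(df, family="bernoulli_logit", seed=2, nsteps=900, burn=300)
        assert fit["rho"].mean > 0.5

    def test_age_corrected_estimate_below_raw_pearson_under_age_trend(self):
        """With a strong age trend and modest stable person effects, the raw
        cross-age Pearson correlation inflates; the hierarchical estimate
        conditions on age and stays near the generating value."""
        df = simulate_retest_data(
            n_subjects=150, n_trials=12, rho=0.5, tau=(0.3, 0.3),
            beta_age=-1.0, sigma=0.5, seed=23,
        )
        agg = df.groupby(["subject_id", "day"])["performance"].mean().unstack()
        raw = retest_pearson(agg[1].to_numpy(), agg[2].to_numpy())
        fit = hierarchical_retest(df, family="lognormal", seed=3, nsteps=1500, burn=500)
        rho = fit["rho"]
        assert raw.coefficient > rho.mean + 0.1
        assert rho.cri_low - 0.1 < 0.5 < rho.cri_high + 0.1

    def test_single_day_data_rejected(self):
        df = simulate_retest_data(n_subjects=30, seed=1)
        with pytest.raises(ValueError):
            hierarchical_retest(df[df["day"] == 1])
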