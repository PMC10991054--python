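# gazetask

A desk-scale simulator and psychometrics toolkit for a browser-based
gaze-understanding task.  In the task, an animated agent watches a target
fall to a hidden spot on the ground; the agent's pupils stay aligned with
the target, and participants (children from age 3, and adults) click where
they think it landed.  The continuous *hedge* version scores each click as
**imprecision** — |click x − target x| in target widths — and the discrete
*box* version scores the choice among k boxes (chance 1/k).

`gazetask` is for researchers who use or adapt this kind of individual-
differences measure and need its computational core testable without human
data.  It provides:

* **Scene geometry** — normalized-viewport scene, forward gaze cueing
  (pupil placement toward the target) and the ideal-observer inverse
  (intersect the eye→pupil rays with the ground line, average the two
  eyes).
* **Constrained trial generation** — balanced agents/colors/target
  positions with no value more than twice in a row, including the fixed
  retest designs (child hedge: ten bins once plus one repeat per adjacent
  bin pair; child box: 5 boxes × 3; adult hedge: 30 trials, bins × 3;
  adult box: 32 trials, boxes × 4).
* **Synthetic participants** — lapse-contaminated noisy ideal observers
  with age-graded angular gaze noise, motor noise, a data-collection-mode
  effect and two test days.
* **Scoring** — imprecision / proportion correct, chance levels, and the
  analysis covariates (symmetric target position, z-age, z-trial).
* **Reliability** — split-half coefficients (first–second, odd–even,
  permutated, Monte-Carlo; optionally stratified by target position;
  Spearman–Brown correction), Pearson test–retest, and the age-corrected
  hierarchical retest model
  `performance ~ age + (0 + day | subject)`, whose person-effect
  correlation ρ is the reliability.
* **Developmental trajectories** — Bayesian mixed models
  `performance ~ age_z + mode + symmetric_position + trial_z +
  (1 + symmetric_position + trial_z | subject)` with lognormal (hedge) or
  Bernoulli-logit (box) families, posterior means with 95% credible
  intervals, and posterior predictions over an age grid.

The hierarchical models are fitted with an ensemble MCMC sampler over an
analytically marginalized likelihood (exact for the lognormal family,
Laplace for the Bernoulli family); see `docs/methods.md` for the models,
priors and validation strategy.

## Worked example

Simulate a fixed-retest hedge cohort (60 children, two sessions), score
it, and estimate reliability three ways:

```bash
gazetask simulate --version hedge --n-subjects 60 --n-days 2 \
    --mode fixed_retest --seed 7 --out raw.csv
gazetask score --in raw.csv --out scored.csv
gazetask reliability --in scored.csv --method odd_even --seed 7 \
    --hierarchical --out rel.json
```

which prints (abbreviated from `rel.json`):

```json
{
  "split_half": {
    "method": "odd_even",
    "coefficient": 0.316,
    "spearman_brown": 0.481,
    "ci_low": 0.092, "ci_high": 0.600
  },
  "test_retest_pearson": { "coefficient": 0.571 },
  "hierarchical_retest": {
    "rho_mean": 0.900, "cri_low": 0.719, "cri_high": 0.995
  }
}
```

Reading the numbers: the raw odd–even correlation of per-subject half
scores is 0.32 over the 14 analyzed test trials (0.48 after Spearman–Brown
projection to full length); the Pearson correlation of day-1 and day-2
mean scores is 0.57; and the hierarchical model — which uses every trial
and removes the shared age trend — estimates the correlation between the
day-specific person effects at 0.90 with a 95% credible interval of
[0.72, 1.00].  The ordering (model-based ≥ aggregate Pearson) is the
expected consequence of avoiding aggregation noise.

The same pipeline is available as a library:

```python
from gazetask import (PopulationConfig, SessionConfig, simulate_cohort,
                      analysis_trials, score_responses, covariates,
                      hierarchical_retest)

records = simulate_cohort(
    PopulationConfig(n_subjects=60, n_days=2, seed=7),
    SessionConfig(version="hedge", mode="fixed_retest", seed=7),
)
scored = covariates(score_responses(analysis_trials(records)))
fit = hierarchical_retest(scored, family="lognormal", seed=7)
print(fit["rho"].mean, fit["rho"].cri_low, fit["rho"].cri_high)
```

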