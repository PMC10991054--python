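# Methods

This note documents the models, algorithms and numerical choices behind
`gazetask`, and what its synthetic data can and cannot show.

## The task being modeled

A cartoon agent looks out of a window at a target (a balloon) that falls to
a random spot on the ground while a hedge blocks the participant's view.
The only usable cue is the agent's gaze: the pupils move so that eye
center, pupil center and target are collinear.  Participants click where
they believe the target landed.  Two versions share this structure:

* **hedge** (continuous): the outcome is *imprecision*, the absolute
  horizontal distance between click and target center, in units of target
  widths.
* **box** (discrete): the target hides in one of k boxes (1-8; 5 for
  children, 8 for adults in the designs built in here) and the outcome is
  a correct/incorrect choice, with chance level 1/k (20% and 12.5%).

## Scene geometry

Everything lives in normalized viewport coordinates: x in [0, 1]
left-to-right, y increasing upward, the ground line at `ground_y`.  The
forward model places each pupil at `eye + r * unit(target - eye)` with
`r = pupil_offset`.  The ideal observer inverts the cue by extending each
eye-to-pupil ray to the ground line and averaging the two per-eye
intersection abscissae; averaging is the symmetric choice and reduces to
the single-eye answer when the eyes coincide.  The forward/inverse round
trip is exact to floating-point error, and the inferred x is strictly
monotone in the target's x for a fixed layout.

Default proportions (eyes at (0.46, 0.70) and (0.54, 0.70), pupil offset
0.02, ground at y = 0.15, target width 0.05) are package conventions: the
source stimuli are scalable vector graphics whose absolute dimensions are
not published, only that relative positions stay constant.  All lengths are
in viewport-width units.  The attention-getter parameters (pupils scale to
130% at 75% opacity for 0.3 s) and the 5-second response prompt are carried
as session metadata; nothing is animated.

## Constrained randomization

Test sequences satisfy the task's published balance rules: agents (3),
target colors (4) and target bins/boxes appear equally often up to a
remainder of one, and no category value occurs more than twice in a row.
Each category sequence is generated independently by rejection sampling: a
balanced multiset is shuffled until the run-length constraint holds
(bounded retries, then a generation error).  This is an algorithmic choice;
only the constraints themselves are given.

Fifteen hedge trials cannot spread evenly over ten bins; the resolution
used for every 15-trial hedge design is the retest study's explicit scheme:
each bin once, plus one repeat drawn from each adjacent pair of bins
({0,1}, {2,3}, ..., {8,9}).  The fixed retest designs reproduce the exact
published counts: child box 5 boxes x 3, adult hedge 30 trials with each
bin x 3, adult box 32 trials with each box x 4.  A fixed-retest sequence is
a pure function of its configuration, so it is constant across
participants and days.

Training ramps visual access down: trial 1 full view, trials 2-3 partial,
any further training trials fully covered.  The fourth training trial's
content is not described in the source material; treating it as a covered
practice trial completes the ramp toward test trials.  Voice-over
instructions mark the first trial of each instruction type — trial 1,
trial 2, and the first test trial — and voice-over trials are excluded
from analysis, mirroring the analysis rule of the original studies.

## Synthetic participants

The response process is a lapse-contaminated noisy ideal observer:

1. with probability `lapse_rate`, click uniformly on [0, 1] (box version:
   choose a box uniformly);
2. otherwise perturb each eye's true gaze angle by Gaussian noise with SD
   `gaze_noise_sd` (degrees), run the ideal-observer inversion on the
   perturbed rays, add Gaussian motor noise, and clamp to the viewport.

Angular noise projected through the ray-ground intersection makes lateral
targets intrinsically harder (the same angular error sweeps more ground),
so the empirical difficulty gradient with target eccentricity emerges from
geometry rather than being imposed — a deliberate qualitative property.

Population structure: `log gaze_noise = intercept + age_slope * age_z +
mode_effect * remote + N(0, tau)`, ages uniform over a configurable range
(36-71 months by default), an optional second test day that multiplies the
noise SD by `day_shift`, and a data-collection-mode covariate.  The
log-linear age model keeps noise positive with diminishing returns.

Parameter defaults are conventions for testing, not measured values.  They
were calibrated once so that synthetic cohorts land in the regime the task
empirically occupies: subject mean imprecision of roughly 0.3-3 target
widths, a clear developmental gradient (the age and mode effect sizes,
-0.32 and -0.30 per SD on the log scale, mirror the reported coefficient
magnitudes of the continuous version), and medium-to-high reliability.
With the initial calibration (tau = 0.3, 5% lapses) uniform lapse clicks —
which can be ~19 target widths off — dominated within-subject variance and
drove split-half reliability toward zero, which is qualitatively unlike the
real task; the shipped defaults (tau = 0.5, 2% lapses) restore a realistic
between/within variance ratio.  What passing tests show is therefore that
the *pipeline* behaves correctly on data with the task's structure; they
say nothing about real children, whose response processes (attention,
strategy shifts, caregiver interference) this generator does not model.

## Scoring and covariates

Imprecision uses the x-coordinate only, scaled by target width; the y
coordinate is recorded but unused.  Analysis covariates: `symmetric_position
= |target_x - 0.5|` (raw viewport units; smaller = more central = easier),
`age_z` standardized against the current dataset's subject-level mean/SD
(stored with the data for reproducibility), `trial_z` the z-scored 0-based
test-trial index (the coding of trial number is not specified upstream).
For lognormal fits, exact zeros are replaced by half the smallest positive
observed value, since the lognormal support excludes zero.

## Reliability estimators

Split-half reliability correlates per-subject mean performance on two
halves of the day-1 trials across subjects.  Methods: `first_second`
(first ceil(n/2) trials vs rest), `odd_even` (parity of trial position),
`permutated` (random partition without replacement per replicate) and
`monte_carlo` (both halves drawn with replacement, each of size n/2).
Resampling methods default to 1,000 replicates and report the mean
coefficient (doubling the replicate count moves the estimate by < 0.01).
Stratification applies the split within each target-position stratum of a
subject's trials and pools, so both halves sample every position.  Raw and
Spearman-Brown-projected (2r/(1+r)) coefficients are both available
because it is ambiguous which convention published figures use.  The 95%
CI is a nonparametric bootstrap over subjects; for resampling methods the
CI uses up to 100 replicates to bound cost while the point estimate uses
all.

Test-retest reliability comes in two forms.  The Pearson form correlates
aggregated day-1 and day-2 scores.  The hierarchical form fits
`performance ~ age + (0 + day | subject)`: day-specific person effects
with an unstructured 2x2 covariance, a fixed age effect, and a lognormal
or Bernoulli-logit observation model.  The posterior of the person-effect
correlation is the age-corrected retest reliability: because age is in the
fixed part, shared developmental maturation cannot masquerade as
stability.  On simulations with a strong age trend, the raw Pearson
estimate inflates above the generating correlation while the hierarchical
estimate stays near it (verified in the test suite).

Under a Gaussian true-score model (subject means with SD tau, trial noise
sigma), the expected odd-even coefficient is the intraclass correlation
tau^2 / (tau^2 + sigma^2/(n/2)); the estimator reproduces this analytic
value within Monte-Carlo error at 500 simulated subjects.

## Trajectory models

The developmental model is
`performance ~ age_z + mode + symmetric_position + trial_z
+ (1 + symmetric_position + trial_z | subject)`,
lognormal family for imprecision (a linear model on log performance) and
Bernoulli-logit for box accuracy.  Mode is coded 0 = in-person supervised
(reference), 1 = remote.

### Estimation

No probabilistic-programming backend is used; both families are fitted by
sampling the marginalized hyperparameter posterior with the
affine-invariant ensemble sampler (emcee), using differential-evolution
moves (80% DE, 20% snooker), which mix well at the 6-12 dimensions
involved.  The log posterior is vectorized across walkers.

* **Lognormal**: the subject random effects are integrated out *exactly* —
  each subject's marginal likelihood is multivariate normal with
  covariance `sigma^2 I + Z Sigma Z'`, evaluated via the Woodbury identity
  and matrix-determinant lemma from per-subject sufficient statistics
  (`Z'Z`, `Z'X`, `Z'y`, `X'X`, `X'y`, `y'y`), so one evaluation costs a
  batch of k x k solves regardless of trial counts.  This is checked in
  the tests against a brute-force multivariate-normal density to machine
  precision.
* **Bernoulli-logit**: each subject's random-effect integral is
  approximated by a Laplace expansion around the conditional mode, found
  by damped Newton iterations batched over (walker, subject) — the same
  approximation class lme4's `glmer` uses.  Accuracy is checked against
  81-node Gauss-Hermite quadrature, and whole fits against `glmer`/`lmer`
  cross-checks run through Rscript.

Priors are weakly informative and documented in code: fixed effects
N(0, 5^2); residual SD HalfNormal(2) (log parametrization with Jacobian);
for the 3x3 random-effect covariance, the Cholesky factor has
N(log 0.3, 1.5^2) log-diagonals and N(0, 1) off-diagonals; for the retest
model's 2x2 covariance, SDs are HalfNormal(1.5) and the correlation —
the quantity of interest — carries a uniform prior on (-1, 1) via a tanh
transform so its posterior is not shrunk by construction.  Hard boxes on
the unconstrained scale (|beta| < 30, log-SDs in (-6, 4)) reject
numerically degenerate proposals.

Defaults: 1,500 steps on max(2*ndim+2, 24) walkers with 500 discarded as
burn-in; summaries report posterior means, central 95% credible intervals,
split-Rhat (walkers treated as chains, halved), and the mean acceptance
fraction.  Problem sizes for the recovery suites — 250 subjects x 15
trials for trajectory coverage, 120 x 15 x 2 for retest recovery — were
chosen to match the scale of the emulated study designs while keeping a
full 20-replicate coverage run in the minutes range.

### Prediction

`predict_trajectory` reports the average subject (random effects at zero)
at reference covariates (dataset-mean symmetric position, mid-session
trial): `exp(eta)` — the conditional median — for the lognormal family and
`logit^-1(eta)` for the Bernoulli family, with 95% CrIs from the posterior
of the fixed effects.  Population-mean predictions would additionally need
the random-effect variance on the response scale; the conditional form was
chosen because it is the monotone, easily interpreted summary the
trajectory figures require.

## Validation strategy

Parameter recovery, not certification: data are simulated from the model
with known generating values (the age coefficient -0.32 reported for the
continuous version serves as a realistic simulation truth) and the fitted
posteriors must cover them — the 95% CrI for the age effect covers the
generating value in >= 90% of 20 seeded replicates, and the retest model's
posterior mean lands within 0.1 of a generating person-effect correlation
of 0.9.  Single-replicate CrI coverage is itself a ~95% event and is not
asserted in isolation.

## File formats

Session files are JSON documents (metadata, trials, responses) validated
with pydantic; the schema is this package's canonical format, not a
reverse-engineered copy of any app's files, whose field names are not
published.  Responses must reference existing trials; missing responses
load as explicit nulls and are excluded by scoring.  Tidy CSV exports are
deterministic (fixed column order, stable sort, floats at 17 significant
digits) so a re-export is byte-identical and values round-trip exactly
when read with `read_tidy`.

## Known limitations

* The response-process parameters are conventions; nothing here is fitted
  to human data, and the generator omits reaction times, y-coordinates of
  clicks, attention drift and caregiver interference.
* The Laplace approximation can bias Bernoulli variance components at very
  small cluster sizes; with the 15-32 trials per subject used here the
  cross-checks against quadrature and glmer agree closely.
* Split-Rhat from ensemble walkers is a rougher diagnostic than multi-chain
  Rhat; values near 1.05 are typical for the default budgets.
* A one-box session cannot satisfy the no-three-in-a-row rule and is
  rejected by the generator.
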