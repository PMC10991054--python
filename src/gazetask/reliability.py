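"""Split-half and test-retest reliability estimators.

Split-half reliability correlates, across subjects, the mean performance on
two halves of each subject's trials.  Four splitting methods are provided:
``first_second`` and ``odd_even`` are single-sample splits, ``permutated``
(random partition without replacement) and ``monte_carlo`` (halves drawn
with replacement) are resampling splits whose coefficient is the mean
Pearson correlation over replicates.  Each method can be stratified by
target position (bin or box), applying the split within each stratum of a
subject's trials before pooling.  Raw coefficients can be projected to
full-test length with the Spearman-Brown formula 2r/(1+r).

Test-retest reliability is offered both as the Pearson correlation of
aggregated day scores and as the age-corrected hierarchical estimate: a
mixed model with a fixed age effect and correlated day-specific person
effects (``performance ~ age + (0 + day | subject)``), whose random-effect
correlation is the reliability coefficient, freed from shared developmental
trends by the age term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import BernoulliGLMM, CorrCov2, FitResult, GaussianLMM
from .scoring import positive_performance

__all__ = [
    "SplitPlan",
    "ReliabilityResult",
    "spearman_brown",
    "split_trials",
    "split_half_coefficient",
    "test_retest_pearson",
    "hierarchical_retest",
    "simulate_retest_data",
]

SINGLE_SAMPLE = {"first_second", "odd_even"}
RESAMPLING = {"permutated", "monte_carlo"}


@dataclass(frozen=True)
class SplitPlan:
    """How to split each subject's trials into two halves."""

    method: Literal["first_second", "odd_even", "permutated", "monte_carlo"] = "odd_even"
    n_replicates: Optional[int] = None  # resolves to 1 (single-sample) or 1000
    stratify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in SINGLE_SAMPLE | RESAMPLING:
            raise ValueError(f"unknown split method {self.method!r}")
        if self.method in SINGLE_SAMPLE:
            if self.n_replicates not in (None, 1):
                raise ValueError(f"{self.method} admits exactly one replicate")
            object.__setattr__(self, "n_replicates", 1)
        elif self.n_replicates is None:
            object.__setattr__(self, "n_replicates", 1000)
        elif self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ReliabilityResult:
    """A reliability coefficient with a bootstrap 95% CI over subjects."""

    coefficient: float
    ci_low: float
    ci_high: float
    method: str
    stratified: bool
    n_subjects: int
    n_replicates: int = 1
    corrected: bool = False

    @property
    def spearman_brown(self) -> float:
        return spearman_brown(self.coefficient)

    def corrected_result(self) -> "ReliabilityResult":
        """The same result with the Spearman-Brown projection applied."""
        return ReliabilityResult(
            coefficient=spearman_brown(self.coefficient),
            ci_low=spearman_brown(self.ci_low),
            ci_high=spearman_brown(self.ci_high),
            method=self.method,
            stratified=self.stratified,
            n_subjects=self.n_subjects,
            n_replicates=self.n_replicates,
            corrected=True,
        )


def spearman_brown(r: float) -> float:
    """Project a half-test correlation to full test length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def _split_positions(
    n: int, method: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    if method == "first_second":
        half = (n + 1) // 2
        return idx[:half], idx[half:]
    if method == "odd_even":
        return idx[idx % 2 == 0], idx[idx % 2 == 1]
    if method == "permutated":
        perm = rng.permutation(n)
        half = (n + 1) // 2
        return np.sort(perm[:half]), np.sort(perm[half:])
    if method == "monte_carlo":
        half = max(n // 2, 1)
        return rng.integers(0, n, size=half), rng.integers(0, n, size=half)
    raise ValueError(method)


def split_trials(
    trials: Sequence,
    plan: SplitPlan,
    rng: Optional[np.random.Generator] = None,
    strata: Optional[Sequence] = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Replicate list of (part1, part2) positional indices into ``trials``.

    With ``plan.stratify`` the split is applied within each stratum (the
    ``strata`` labels, e.g. target bin) and the parts pooled, so both
    halves sample every target position.
    """
    n = len(trials)
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    if plan.stratify:
        if strata is None:
            raise ValueError("stratified splits need stratum labels")
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata must align with trials")
    out = []
    for _ in range(plan.n_replicates):
        if not plan.stratify:
            out.append(_split_positions(n, plan.method, rng))
            continue
        part1, part2 = [], []
        for value in pd.unique(strata):
            pos = np.flatnonzero(strata == value)
            if len(pos) < 1:
                raise ValueError("empty stratum")
            a, b = _split_positions(len(pos), plan.method, rng)
            part1.append(pos[a])
            part2.append(pos[b])
        out.append((np.sort(np.concatenate(part1)), np.sort(np.concatenate(part2))))
    return out


def _half_scores(
    df: pd.DataFrame, plan: SplitPlan, performance: str, subject: str, stratum_col: Optional[str]
) -> np.ndarray:
    """(n_replicates, n_subjects, 2) mean performance per half."""
    rng = np.random.default_rng(plan.seed)
    if plan.stratify and stratum_col is None:
        for candidate in ("bin", "box"):
            if candidate in df and df[candidate].notna().any():
                stratum_col = candidate
                break
        if stratum_col is None:
            raise ValueError("no bin/box column found for stratification")
    subjects = df[subject].unique()
    scores = np.empty((plan.n_replicates, len(subjects), 2))
    for j, subj in enumerate(subjects):
        sub = df[df[subject] == subj]
        perf = sub[performance].to_numpy(float)
        strata = sub[stratum_col].to_numpy() if plan.stratify else None
        for rep, (a, b) in enumerate(split_trials(perf, plan, rng=rng, strata=strata)):
            if len(a) == 0 or len(b) == 0:
                raise ValueError(f"subject {subj!r} has an empty split half")
            scores[rep, j, 0] = perf[a].mean()
            scores[rep, j, 1] = perf[b].mean()
    return scores


def _pearson_by_rep(scores: np.ndarray) -> np.ndarray:
    """Pearson r for each replicate of an (R, S, 2) half-score array."""
    x = scores[..., 0] - scores[..., 0].mean(axis=1, keepdims=True)
    y = scores[..., 1] - scores[..., 1].mean(axis=1, keepdims=True)
    denom = np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x * y).sum(axis=1) / denom


def split_half_coefficient(
    df: pd.DataFrame,
    plan: SplitPlan,
    performance: str = "performance",
    subject: str = "subject_id",
    stratum_col: Optional[str] = None,
    ci_bootstrap: int = 500,
    ci_max_replicates: int = 100,
) -> ReliabilityResult:
    """Split-half reliability: Pearson r of per-subject half scores.

    Resampling methods report the mean coefficient over replicates.  The
    95% CI is a nonparametric bootstrap over subjects (resampling methods
    use up to ``ci_max_replicates`` replicates for the CI to bound cost).
    """
    n_subjects = df[subject].nunique()
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    scores = _half_scores(df, plan, performance, subject, stratum_col)
    r_by_rep = _pearson_by_rep(scores)
    if np.isnan(r_by_rep).all():
        raise ValueError("correlation undefined: zero variance in a split half")
    coefficient = float(np.nanmean(r_by_rep))

    rng = np.random.default_rng(plan.seed + 1)
    sub_scores = scores[: min(plan.n_replicates, ci_max_replicates)]
    boots = np.empty(ci_bootstrap)
    for i in range(ci_bootstrap):
        take = rng.integers(0, n_subjects, size=n_subjects)
        boots[i] = np.nanmean(_pearson_by_rep(sub_scores[:, take, :]))
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return ReliabilityResult(
        coefficient=coefficient,
        ci_low=float(lo),
        ci_high=float(hi),
        method=plan.method,
        stratified=plan.stratify,
        n_subjects=n_subjects,
        n_replicates=plan.n_replicates,
    )


def test_retest_pearson(
    day1_scores: Sequence[float],
    day2_scores: Sequence[float],
    ci_bootstrap: int = 1000,
    seed: int = 0,
) -> ReliabilityResult:
    """Pearson correlation of paired per-subject day scores, bootstrap CI."""
    x = np.asarray(day1_scores, float)
    y = np.asarray(day2_scores, float)
    if x.shape != y.shape:
        raise ValueError("day scores must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    scores = np.stack([x, y], axis=-1)[None]
    r = float(_pearson_by_rep(scores)[0])
    if np.isnan(r):
        raise ValueError("correlation undefined: zero variance")
    rng = np.random.default_rng(seed)
    boots = np.empty(ci_bootstrap)
    for i in range(ci_bootstrap):
        take = rng.integers(0, n, size=n)
        boots[i] = _pearson_by_rep(scores[:, take, :])[0]
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return ReliabilityResult(
        coefficient=r,
        ci_low=float(lo),
        ci_high=float(hi),
        method="test_retest_pearson",
        stratified=False,
        n_subjects=n,
    )


def hierarchical_retest(
    df: pd.DataFrame,
    family: Literal["lognormal", "bernoulli_logit"] = "lognormal",
    seed: int = 0,
    nsteps: int = 1500,
    burn: int = 500,
    nwalkers: Optional[int] = None,
) -> FitResult:
    """Age-corrected test-retest reliability from a random-slope mixed model.

    Fits ``performance ~ age + (0 + day | subject)`` with day-specific
    person effects; the posterior of their correlation (``rho`` in the
    returned fit) is the age-independent retest reliability.  The lognormal
    family models log imprecision, the Bernoulli family correct choices.
    """
    days = np.sort(df["day"].unique())
    if len(days) != 2:
        raise ValueError("hierarchical retest needs exactly two test days")
    age = df["age_z"].to_numpy(float) if "age_z" in df else np.zeros(len(df))
    X = np.column_stack([np.ones(len(df)), age])
    Z = np.column_stack([(df["day"] == d).to_numpy(float) for d in days])
    groups = pd.factorize(df["subject_id"])[0]
    counts = df.groupby(["subject_id", "day"]).size().unstack(fill_value=0)
    if (counts == 0).any().any():
        raise ValueError("every subject needs trials on both days")
    y = df["performance"].to_numpy(float)
    cov = CorrCov2(names=("day1", "day2"))
    if family == "lognormal":
        if np.any(y < 0):
            raise ValueError("lognormal family needs non-negative performance")
        model = GaussianLMM(
            X, Z, np.log(positive_performance(y)), groups,
            fixed_names=["intercept", "age_z"], cov=cov,
        )
    elif family == "bernoulli_logit":
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("bernoulli_logit family needs 0/1 performance")
        model = BernoulliGLMM(
            X, Z, y, groups, fixed_names=["intercept", "age_z"], cov=cov
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    return model.sample(seed=seed, nwalkers=nwalkers, nsteps=nsteps, burn=burn)


def simulate_retest_data(
    n_subjects: int = 120,
    n_trials: int = 15,
    rho: float = 0.9,
    tau: tuple[float, float] = (0.5, 0.5),
    beta_intercept: float = 0.3,
    beta_age: float = -0.32,
    sigma: float = 0.6,
    family: Literal["lognormal", "bernoulli_logit"] = "lognormal",
    age_range: tuple[int, int] = (36, 71),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-day data directly from the retest model.

    Day-specific person effects are drawn from a bivariate normal with SDs
    ``tau`` and correlation ``rho`` — the generating value the fitted
    ``rho`` posterior should recover.
    """
    rng = np.random.default_rng(seed)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_subjects)
    age_z = (ages - ages.mean()) / (ages.std() or 1.0)
    cov = np.array(
        [[tau[0] ** 2, rho * tau[0] * tau[1]], [rho * tau[0] * tau[1], tau[1] ** 2]]
    )
    u = rng.multivariate_normal(np.zeros(2), cov, size=n_subjects)
    rows = []
    for i in range(n_subjects):
        for day in (1, 2):
            eta = beta_intercept + beta_age * age_z[i] + u[i, day - 1]
            if family == "lognormal":
                perf = np.exp(eta + sigma * rng.standard_normal(n_trials))
            else:
                p = 1.0 / (1.0 + np.exp(-eta))
                perf = (rng.uniform(size=n_trials) < p).astype(float)
            for t in range(n_trials):
                rows.append(
                    {
                        "subject_id": f"s{i:04d}",
                        "age_months": float(ages[i]),
                        "age_z": float(age_z[i]),
                        "day": day,
                        "trial_index": t,
                        "performance": float(perf[t]),
                    }
                )
    return pd.DataFrame(rows)
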