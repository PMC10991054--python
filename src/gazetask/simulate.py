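"""Synthetic participants: noisy ideal observers clicking on the scene.

The response process is a lapse-contaminated noisy ideal observer.  On a
lapse the responder ignores the cue and answers uniformly at random.
Otherwise the true gaze angle of each eye is perturbed by Gaussian angular
noise, the perturbed rays are intersected with the ground line exactly as
the ideal observer would, and Gaussian motor noise is added to the
resulting click, which is clamped to the viewport.  Because a fixed angular
error projects to a larger horizontal error for more lateral targets, the
empirical difficulty gradient with target eccentricity emerges from the
geometry rather than being imposed.

Population structure mirrors the study design being emulated: ages sampled
over a configurable range (children 36-71 months by default), a log-linear
age trend on gaze noise, a data-collection-mode effect, between-subject
heterogeneity, and an optional second test day with a multiplicative
precision shift.  All response-process parameter defaults are package
conventions for testing; none are measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .geometry import GazePose, GeometryError, Point2D, SceneLayout, infer_ground_x
from .sessions import SessionConfig, TrialSpec, fixed_retest_sequence, generate_session

__all__ = [
    "ParticipantParams",
    "PopulationConfig",
    "simulate_click",
    "simulate_box_choice",
    "draw_participants",
    "simulate_cohort",
    "analysis_trials",
]


@dataclass(frozen=True)
class ParticipantParams:
    """Latent response-process parameters of one synthetic subject."""

    subject_id: str
    age_months: float
    mode: Literal["in_person", "remote"] = "in_person"
    gaze_noise_sd: float = 5.0  # degrees of angular error on each eye's gaze
    motor_noise_sd: float = 0.01  # viewport units added to the click
    lapse_rate: float = 0.05
    day_shift: float = 1.0  # multiplies gaze noise SD on day 2 (<1: more precise)

    def __post_init__(self) -> None:
        if self.gaze_noise_sd <= 0:
            raise ValueError("gaze_noise_sd must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")

    def gaze_sd_for_day(self, day: int) -> float:
        return self.gaze_noise_sd * (self.day_shift if day == 2 else 1.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Age-graded population distribution of the latent parameters.

    Gaze noise follows ``log sd = intercept + age_slope * age_z +
    mode_effect * remote + N(0, subject_sd)``; the log-linear form keeps the
    noise positive with diminishing returns over age.  The age slope and
    mode effect defaults are set to the effect magnitudes reported for the
    continuous task version so that simulated cohorts show a realistic
    developmental gradient; all remaining defaults are testing conventions.
    """

    n_subjects: int = 120
    age_range: tuple[int, int] = (36, 71)  # months, inclusive
    log_noise_intercept: float = math.log(5.0)  # log degrees at the mean age
    age_slope: float = -0.32  # per SD of age, on log gaze noise
    subject_sd: float = 0.50  # between-subject SD (tau) on log gaze noise
    mode_effect: float = -0.30  # remote vs in-person, on log gaze noise
    remote_fraction: float = 0.0
    lapse_rate: float = 0.02
    motor_noise_sd: float = 0.01
    n_days: int = 1
    day_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("subject_sd (tau) must be >= 0")
        if self.n_days not in (1, 2):
            raise ValueError("n_days must be 1 or 2")


def _perturbed_pose(
    layout: SceneLayout, target_x: float, sd_deg: float, rng: np.random.Generator
) -> GazePose:
    """Gaze pose after adding angular noise to each eye's true direction.

    Noise draws are repeated per eye until the ray points downward; with
    the steep viewing geometry and realistic noise levels this truncation
    is negligible.
    """
    target = Point2D(target_x, layout.ground_y)
    pupils = []
    for eye in layout.eye_centers:
        angle = math.atan2(target.y - eye.y, target.x - eye.x)
        for _ in range(1000):
            theta = angle + math.radians(sd_deg) * rng.standard_normal()
            if math.sin(theta) < 0.0:
                break
        else:
            raise GeometryError("could not draw a downward-pointing gaze ray")
        pupils.append(
            Point2D(
                eye.x + layout.pupil_offset * math.cos(theta),
                eye.y + layout.pupil_offset * math.sin(theta),
            )
        )
    return GazePose(pupil_centers=(pupils[0], pupils[1]))


def simulate_click(
    params: ParticipantParams,
    trial: TrialSpec,
    layout: SceneLayout,
    rng: np.random.Generator,
    day: int = 1,
) -> float:
    """One click x-coordinate on a partial- or no-visibility trial."""
    if trial.visibility == "full":
        # target visible: click straight on it, motor noise only
        x = trial.target_x + params.motor_noise_sd * rng.standard_normal()
        return float(min(max(x, 0.0), 1.0))
    if rng.uniform() < params.lapse_rate:
        return float(rng.uniform(0.0, 1.0))
    pose = _perturbed_pose(layout, trial.target_x, params.gaze_sd_for_day(day), rng)
    x = infer_ground_x(layout, pose) + params.motor_noise_sd * rng.standard_normal()
    return float(min(max(x, 0.0), 1.0))


def simulate_box_choice(
    params: ParticipantParams,
    trial: TrialSpec,
    layout: SceneLayout,
    rng: np.random.Generator,
    day: int = 1,
) -> int:
    """Chosen 0-based box: the box containing the simulated click (lapses
    choose uniformly among boxes)."""
    if trial.box is None:
        raise ValueError("simulate_box_choice requires a box-version trial")
    if trial.visibility != "full" and rng.uniform() < params.lapse_rate:
        return int(rng.integers(0, layout.n_boxes))
    lapse_free = ParticipantParams(
        subject_id=params.subject_id,
        age_months=params.age_months,
        mode=params.mode,
        gaze_noise_sd=params.gaze_noise_sd,
        motor_noise_sd=params.motor_noise_sd,
        lapse_rate=0.0,
        day_shift=params.day_shift,
    )
    return layout.box_for_x(simulate_click(lapse_free, trial, layout, rng, day=day))


def draw_participants(pop: PopulationConfig, rng: np.random.Generator) -> list[ParticipantParams]:
    """Draw each subject's latent parameters once from the population model."""
    ages = rng.integers(pop.age_range[0], pop.age_range[1] + 1, size=pop.n_subjects)
    age_sd = ages.std() or 1.0
    age_z = (ages - ages.mean()) / age_sd
    remote = rng.uniform(size=pop.n_subjects) < pop.remote_fraction
    log_sd = (
        pop.log_noise_intercept
        + pop.age_slope * age_z
        + pop.mode_effect * remote
        + pop.subject_sd * rng.standard_normal(pop.n_subjects)
    )
    return [
        ParticipantParams(
            subject_id=f"s{i:04d}",
            age_months=float(ages[i]),
            mode="remote" if remote[i] else "in_person",
            gaze_noise_sd=float(np.exp(log_sd[i])),
            motor_noise_sd=pop.motor_noise_sd,
            lapse_rate=pop.lapse_rate,
            day_shift=pop.day_shift,
        )
        for i in range(pop.n_subjects)
    ]


def simulate_cohort(
    pop: PopulationConfig,
    session: SessionConfig,
    layout: Optional[SceneLayout] = None,
) -> pd.DataFrame:
    """Simulate one response record per subject x day x test trial.

    Latent parameters are drawn once per subject; fixed-retest designs
    reuse a single trial sequence across subjects and days, while
    randomized designs draw a fresh session per subject and day.  The
    result is reproducible from ``pop.seed``.
    """
    if pop.n_subjects <= 1 and pop.n_days == 2:
        raise ValueError("reliability designs need more than one subject")
    layout = layout or session.layout()
    root = np.random.SeedSequence(pop.seed)
    param_seq, response_seq, session_seq = root.spawn(3)
    participants = draw_participants(pop, np.random.default_rng(param_seq))
    response_rng = np.random.default_rng(response_seq)
    session_rng = np.random.default_rng(session_seq)

    fixed = fixed_retest_sequence(session, layout) if session.mode == "fixed_retest" else None
    rows = []
    for params in participants:
        for day in range(1, pop.n_days + 1):
            if fixed is not None:
                trials = fixed
            else:
                cfg = SessionConfig(
                    version=session.version,
                    cohort=session.cohort,
                    mode=session.mode,
                    n_training=session.n_training,
                    n_test=session.n_test,
                    n_bins=session.n_bins,
                    n_boxes=session.n_boxes,
                    max_run=session.max_run,
                    seed=int(session_rng.integers(0, 2**31 - 1)),
                )
                trials = generate_session(cfg, layout)
            test_trials = [t for t in trials if t.phase == "test"]
            for j, trial in enumerate(test_trials):
                row = {
                    "subject_id": params.subject_id,
                    "age_months": params.age_months,
                    "mode": params.mode,
                    "day": day,
                    "trial_index": j,
                    "voiceover": trial.voiceover,
                    "version": session.version,
                    "target_x": trial.target_x,
                    "target_width": layout.target_width,
                    "bin": trial.bin,
                    "box": trial.box,
                }
                if session.version == "hedge":
                    row["click_x"] = simulate_click(params, trial, layout, response_rng, day=day)
                    row["chosen_box"] = None
                else:
                    row["click_x"] = None
                    row["chosen_box"] = simulate_box_choice(
                        params, trial, layout, response_rng, day=day
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def analysis_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to analyzable test trials (drop voice-over instruction trials)."""
    if "voiceover" in records:
        return records[~records["voiceover"].astype(bool)].copy()
    return records.copy()
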