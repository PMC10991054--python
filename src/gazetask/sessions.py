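"""Constrained randomization of training and test trial sequences.

Test sequences satisfy the task's balance rules: every agent, target color
and target bin/box appears equally often (up to a remainder of one when the
trial count is not divisible), and no category value repeats on more than
two consecutive trials.  Child sessions use 4 training + 15 test trials.
The fixed retest designs use the exact published trial counts: child hedge
sessions place the target once in each of the ten bins plus one repeat from
each adjacent bin pair; child box sessions use five boxes three times each;
adult retest sessions use 30 hedge trials (ten bins three times) or 32 box
trials (eight boxes four times).

Sequences are produced by rejection sampling: a balanced multiset of
category values is shuffled until the run-length constraint holds, with a
bounded number of retries.  Every draw comes from one seeded generator, so
a session is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Literal, Optional, Sequence

import numpy as np

from .geometry import SceneLayout

__all__ = [
    "GenerationError",
    "TrialSpec",
    "SessionConfig",
    "generate_session",
    "fixed_retest_sequence",
    "training_block",
    "sample_coordinate_in_bin",
    "max_run_length",
]

AGENTS = ("sheep", "monkey", "pig")
COLORS = ("blue", "green", "yellow", "red")

Phase = Literal["training_full", "training_partial", "training_covered", "test"]
Visibility = Literal["full", "partial", "none"]


class GenerationError(RuntimeError):
    """Constraint set unsatisfiable within the retry budget."""


@dataclass(frozen=True)
class TrialSpec:
    """One generated trial: categorical design cells plus the sampled target."""

    index: int
    phase: Phase
    agent: str
    color: str
    target_x: float
    visibility: Visibility
    voiceover: bool
    bin: Optional[int] = None
    box: Optional[int] = None


@dataclass(frozen=True)
class SessionConfig:
    """Design parameters of one session.

    ``n_test=None`` resolves to the cohort default: 15 for children, and for
    adult fixed-retest sessions 30 (hedge) or 32 (box).  ``n_boxes`` defaults
    to 5 for children and 8 for adults.
    """

    version: Literal["hedge", "box"] = "hedge"
    cohort: Literal["child", "adult"] = "child"
    mode: Literal["randomized", "fixed_retest"] = "randomized"
    n_training: int = 4
    n_test: Optional[int] = None
    n_bins: int = 10
    n_boxes: Optional[int] = None
    agents: Sequence[str] = AGENTS
    colors: Sequence[str] = COLORS
    max_run: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boxes is None:
            object.__setattr__(self, "n_boxes", 5 if self.cohort == "child" else 8)
        if self.n_test is None:
            if self.cohort == "adult" and self.mode == "fixed_retest":
                object.__setattr__(self, "n_test", 30 if self.version == "hedge" else 32)
            else:
                object.__setattr__(self, "n_test", 15)

    def layout(self) -> SceneLayout:
        return SceneLayout(n_bins=self.n_bins, n_boxes=self.n_boxes)


def max_run_length(values: Sequence) -> int:
    """Length of the longest run of identical consecutive values."""
    return max((len(list(g)) for _, g in groupby(values)), default=0)


def _balanced_multiset(levels: Sequence, n: int, rng: np.random.Generator) -> list:
    """n values over the levels with counts differing by at most one."""
    k = len(levels)
    base, rem = divmod(n, k)
    counts = {lev: base for lev in levels}
    for lev in rng.choice(len(levels), size=rem, replace=False):
        counts[levels[int(lev)]] += 1
    return [lev for lev in levels for _ in range(counts[lev])]


def _arrange(multiset: list, rng: np.random.Generator, max_run: int, max_tries: int = 10_000) -> list:
    """Shuffle a multiset until no value runs longer than max_run."""
    values = list(multiset)
    for _ in range(max_tries):
        rng.shuffle(values)
        if max_run_length(values) <= max_run:
            return values
    raise GenerationError(
        f"could not arrange {len(values)} trials with max run {max_run} "
        f"within {max_tries} shuffles"
    )


def _bin_multiset(n_test: int, n_bins: int, rng: np.random.Generator) -> list[int]:
    """Target-bin multiset for a hedge session.

    Exact multiples of ``n_bins`` give equal counts.  The 15-trials-over-
    10-bins child design uses each bin once plus one repeat drawn from each
    adjacent pair (bins {0,1}, {2,3}, ...).  Any other count falls back to
    balance-within-one.
    """
    if n_test % n_bins == 0:
        return [b for b in range(n_bins) for _ in range(n_test // n_bins)]
    if n_bins % 2 == 0 and n_test == n_bins + n_bins // 2:
        repeats = [int(rng.integers(2 * p, 2 * p + 2)) for p in range(n_bins // 2)]
        return list(range(n_bins)) + repeats
    return _balanced_multiset(list(range(n_bins)), n_test, rng)


def sample_coordinate_in_bin(bin_index: int, layout: SceneLayout, rng: np.random.Generator) -> float:
    """Uniform x strictly inside the half-open interval of a 0-based bin."""
    lo, hi = layout.bin_interval(bin_index)
    return float(rng.uniform(lo, hi))


def _sample_in_box(box_index: int, layout: SceneLayout, rng: np.random.Generator) -> float:
    lo, hi = layout.box_interval(box_index)
    return float(rng.uniform(lo, hi))


def _training_trials(
    config: SessionConfig, layout: SceneLayout, rng: np.random.Generator
) -> list[TrialSpec]:
    if config.n_training < 3:
        raise GenerationError("at least 3 training trials are required (full, partial, partial)")
    trials = []
    for i in range(config.n_training):
        if i == 0:
            phase, visibility = "training_full", "full"
        elif i <= 2:
            phase, visibility = "training_partial", "partial"
        else:
            phase, visibility = "training_covered", "none"
        agent = str(rng.choice(config.agents))
        color = str(rng.choice(config.colors))
        if config.version == "hedge":
            b = int(rng.integers(0, layout.n_bins))
            x = sample_coordinate_in_bin(b, layout, rng)
            loc = {"bin": b}
        else:
            b = int(rng.integers(0, layout.n_boxes))
            x = _sample_in_box(b, layout, rng)
            loc = {"box": b}
        trials.append(
            TrialSpec(
                index=i,
                phase=phase,
                agent=agent,
                color=color,
                target_x=x,
                visibility=visibility,
                voiceover=i in (0, 1),  # first full-access and first partial-access trial
                **loc,
            )
        )
    return trials


def generate_session(config: SessionConfig, layout: Optional[SceneLayout] = None) -> list[TrialSpec]:
    """Generate a full session (training block followed by test trials).

    Over the test trials, agent and color counts are balanced within one,
    target bins/boxes follow the version-specific design, and no category
    value occurs more than ``config.max_run`` times in a row.  The result is
    a deterministic function of ``config`` (including its seed).
    """
    layout = layout or config.layout()
    rng = np.random.default_rng(config.seed)
    trials = _training_trials(config, layout, rng)

    n = config.n_test
    agents = _arrange(_balanced_multiset(list(config.agents), n, rng), rng, config.max_run)
    colors = _arrange(_balanced_multiset(list(config.colors), n, rng), rng, config.max_run)
    if config.version == "hedge":
        locations = _arrange(_bin_multiset(n, layout.n_bins, rng), rng, config.max_run)
    else:
        locations = _arrange(
            _balanced_multiset(list(range(layout.n_boxes)), n, rng), rng, config.max_run
        )

    offset = config.n_training
    for i in range(n):
        loc = locations[i]
        if config.version == "hedge":
            x = sample_coordinate_in_bin(loc, layout, rng)
            where = {"bin": loc}
        else:
            x = _sample_in_box(loc, layout, rng)
            where = {"box": loc}
        trials.append(
            TrialSpec(
                index=offset + i,
                phase="test",
                agent=agents[i],
                color=colors[i],
                target_x=x,
                visibility="none",
                voiceover=i == 0,  # voice-over on the first test trial
                **where,
            )
        )
    return trials


def training_block(config: SessionConfig, layout: Optional[SceneLayout] = None) -> list[TrialSpec]:
    """The training trials of a session (full, partial, partial, covered...)."""
    layout = layout or config.layout()
    rng = np.random.default_rng(config.seed)
    return _training_trials(config, layout, rng)


def fixed_retest_sequence(
    config: SessionConfig, layout: Optional[SceneLayout] = None
) -> list[TrialSpec]:
    """The retest sequence: randomized once, then constant across participants.

    Identical output for identical configuration; both test days of every
    subject reuse this single sequence.
    """
    if config.mode != "fixed_retest":
        raise GenerationError("fixed_retest_sequence requires mode='fixed_retest'")
    return generate_session(config, layout)
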