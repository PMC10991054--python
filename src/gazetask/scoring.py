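"""Outcome measures and analysis covariates.

The continuous ("hedge") version scores each response as *imprecision*: the
absolute horizontal distance between click and target center, in units of
target widths, so an imprecision of 1 means the click landed one target
width to the left or right of the true center.  The discrete ("box")
version scores a binary correct/incorrect choice, summarized as the
proportion correct; guessing among k boxes succeeds with probability 1/k.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "imprecision",
    "proportion_correct",
    "chance_level",
    "covariates",
    "score_responses",
    "positive_performance",
]


def imprecision(click_x, target_x, target_width: float):
    """|click_x - target_x| scaled by the target width.

    Accepts scalars or arrays; invariant to a common rescaling of all
    coordinates and the width.
    """
    if target_width <= 0:
        raise ValueError("target_width must be positive")
    return np.abs(np.asarray(click_x) - np.asarray(target_x)) / target_width


def chance_level(n_boxes: int) -> float:
    """Expected accuracy of a uniform guesser among ``n_boxes`` boxes."""
    if n_boxes < 1:
        raise ValueError("n_boxes must be >= 1")
    return 1.0 / n_boxes


def proportion_correct(records: pd.DataFrame, by: str | Iterable[str] = "subject_id") -> pd.Series:
    """Mean of the correct indicator per subject (or any grouping)."""
    if "correct" not in records:
        raise ValueError("records must carry a 'correct' column (box version)")
    return records.groupby(by, sort=True)["correct"].mean()


def score_responses(records: pd.DataFrame, version: Optional[str] = None) -> pd.DataFrame:
    """Attach the version-appropriate ``performance`` column.

    Hedge: performance = imprecision of the click (rows without a click are
    dropped).  Box: a ``correct`` 0/1 column is derived from the chosen and
    true box, and performance aliases it.
    """
    version = version or (records["version"].iloc[0] if "version" in records else None)
    if version not in {"hedge", "box"}:
        raise ValueError(f"unknown version {version!r}")
    out = records.copy()
    if version == "hedge":
        out = out[out["click_x"].notna()].copy()
        out["performance"] = imprecision(
            out["click_x"].to_numpy(), out["target_x"].to_numpy(), float(out["target_width"].iloc[0])
        ) if len(out) else np.array([])
    else:
        out = out[out["chosen_box"].notna()].copy()
        out["correct"] = (out["chosen_box"].astype(int) == out["box"].astype(int)).astype(int)
        out["performance"] = out["correct"].astype(float)
    return out


def covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Add trial- and subject-level analysis covariates.

    symmetric_position
        |target_x - 0.5|: the target's absolute distance from the screen
        center; smaller values mean more central, easier targets.
    age_z
        age in months z-scored against this dataset's subject-level mean/SD
        (stored in ``DataFrame.attrs`` for reproducibility).  Zero when the
        dataset has a single age.
    trial_z
        z-scored 0-based test-trial number.
    """
    out = records.copy()
    out["symmetric_position"] = np.abs(out["target_x"] - 0.5)
    subjects = out.drop_duplicates("subject_id")
    age_mean = float(subjects["age_months"].mean())
    age_sd = float(subjects["age_months"].std(ddof=0))
    out["age_z"] = 0.0 if age_sd == 0 else (out["age_months"] - age_mean) / age_sd
    out.attrs["age_mean"] = age_mean
    out.attrs["age_sd"] = age_sd
    t = out["trial_index"].astype(float)
    t_sd = float(t.std(ddof=0))
    out["trial_z"] = 0.0 if t_sd == 0 else (t - t.mean()) / t_sd
    return out


def positive_performance(values: np.ndarray) -> np.ndarray:
    """Replace exact zeros by half the smallest positive value.

    The lognormal likelihood has support on (0, inf); a click exactly on
    the target center would otherwise be unusable.
    """
    values = np.asarray(values, dtype=float).copy()
    if np.any(values < 0):
        raise ValueError("performance values must be non-negative")
    zero = values == 0
    if zero.any():
        positive = values[~zero]
        if positive.size == 0:
            raise ValueError("all performance values are zero")
        values[zero] = positive.min() / 2.0
    return values
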