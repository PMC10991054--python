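"""Session-file schema and tidy exports.

A session file is the JSON document a task run produces: metadata
(subject, mode, device, app presentation constants), the full list of
generated trials, and the recorded responses.  The schema here is the
package's canonical format, validated with pydantic; it is not a
reverse-engineered copy of any particular web app's files.  Missing
responses are kept as explicit nulls and excluded by scoring.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .sessions import TrialSpec

__all__ = [
    "SchemaError",
    "AppParameters",
    "SessionMetadata",
    "TrialModel",
    "ResponseModel",
    "SessionFile",
    "read_session",
    "write_session",
    "session_from_trials",
    "session_to_records",
    "export_tidy",
    "read_tidy",
]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A session document violates the schema."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AppParameters(_Model):
    """Presentation constants carried as metadata (not animated here)."""

    attention_getter_scale: float = 1.30  # pupil enlargement during attention-getter
    attention_getter_opacity: float = 0.75
    attention_getter_duration_s: float = 0.3
    prompt_timeout_s: float = 5.0  # audio reminder if no response within 5 s


class SessionMetadata(_Model):
    subject_id: str
    version: Literal["hedge", "box"]
    schema_version: str = SCHEMA_VERSION
    age_months: Optional[float] = None
    mode: Literal["in_person", "remote"] = "in_person"
    day: int = 1
    device: Optional[str] = None
    timestamp: Optional[str] = None
    app: AppParameters = Field(default_factory=AppParameters)


class TrialModel(_Model):
    index: int = Field(ge=0)
    phase: Literal["training_full", "training_partial", "training_covered", "test"]
    agent: str
    color: str
    target_x: float = Field(ge=0.0, le=1.0)
    visibility: Literal["full", "partial", "none"]
    voiceover: bool
    bin: Optional[int] = None
    box: Optional[int] = None


class ResponseModel(_Model):
    trial_index: int = Field(ge=0)
    click_x: Optional[float] = None
    click_y: Optional[float] = None
    chosen_box: Optional[int] = None
    response_time_s: Optional[float] = None


class SessionFile(_Model):
    metadata: SessionMetadata
    trials: list[TrialModel]
    responses: list[ResponseModel] = Field(default_factory=list)

    @model_validator(mode="after")
    def _responses_reference_trials(self) -> "SessionFile":
        n = len(self.trials)
        for r in self.responses:
            if r.trial_index >= n:
                raise ValueError(
                    f"response references trial {r.trial_index} but session has {n} trials"
                )
        return self


def read_session(path: str | Path) -> SessionFile:
    """Load and validate a session document; schema violations raise
    :class:`SchemaError` with field-level messages."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    try:
        return SessionFile.model_validate(payload)
    except ValidationError as exc:
        raise SchemaError(str(exc)) from exc


def write_session(session: SessionFile, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(session.model_dump(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def session_from_trials(
    trials: list[TrialSpec],
    subject_id: str,
    version: Literal["hedge", "box"],
    responses: Optional[list[ResponseModel]] = None,
    **metadata,
) -> SessionFile:
    """Wrap generated trials (and optional responses) into a session file."""
    return SessionFile(
        metadata=SessionMetadata(subject_id=subject_id, version=version, **metadata),
        trials=[TrialModel(**vars(t)) for t in trials],
        responses=responses or [],
    )


def session_to_records(session: SessionFile, target_width: float = 0.05) -> pd.DataFrame:
    """One row per responded trial, ready for scoring.

    Trials without a response are kept with null click/choice so scoring
    can count and exclude them explicitly.
    """
    meta = session.metadata
    by_trial = {r.trial_index: r for r in session.responses}
    rows = []
    for t in session.trials:
        r = by_trial.get(t.index)
        rows.append(
            {
                "subject_id": meta.subject_id,
                "age_months": meta.age_months,
                "mode": meta.mode,
                "day": meta.day,
                "version": meta.version,
                "trial_index": t.index,
                "phase": t.phase,
                "voiceover": t.voiceover,
                "bin": t.bin,
                "box": t.box,
                "target_x": t.target_x,
                "target_width": target_width,
                "click_x": None if r is None else r.click_x,
                "chosen_box": None if r is None else r.chosen_box,
            }
        )
    return pd.DataFrame(rows)


_COLUMN_ORDER = [
    "subject_id",
    "age_months",
    "mode",
    "day",
    "trial_index",
    "phase",
    "voiceover",
    "version",
    "bin",
    "box",
    "target_x",
    "target_width",
    "click_x",
    "chosen_box",
    "correct",
    "performance",
    "symmetric_position",
    "age_z",
    "trial_z",
]


def export_tidy(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic UTF-8 CSV: stable column order, stable row order.

    Floats are written with 17 significant digits, so values survive a CSV
    round trip bit-exactly and a re-export is byte-identical.
    """
    cols = [c for c in _COLUMN_ORDER if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    out = df[cols].copy()
    sort_cols = [c for c in ("subject_id", "day", "trial_index") if c in out.columns]
    if sort_cols:
        out = out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_tidy(path: str | Path) -> pd.DataFrame:
    """Read a tidy CSV with a correctly-rounded float parser, so values
    written by :func:`export_tidy` come back bit-exact."""
    return pd.read_csv(path, float_precision="round_trip")
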