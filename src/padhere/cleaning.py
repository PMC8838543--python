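"""Daily-log cleaning: plausibility bounds and zero-substitution.

Self-reported daily values are cleaned with two independent rules:

* a *missing* entry (nothing submitted for that metric that day) is scored
  as 0 for goal computation;
* a *submitted but implausible* entry — daily steps below 1000 or above
  30,000, or more than 1080 MVPA minutes in a day — is likewise scored 0.

Crucially, cleaning never alters the submission indicator: a submitted but
implausible entry still counts as self-monitoring for that day, because
self-monitoring adherence is defined by record submission (any value,
including 0), independently of the value's plausibility.

The module works both on single :class:`DailyRecord` objects (``clean_day``)
and vectorized on long-format pandas DataFrames (``clean_logs``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DuplicateRecordError, MalformedRecordError
from .states import DAYS_PER_WEEK, GOAL_WEEKS

#: Plausibility bounds (inclusive): daily steps outside [1000, 30000] and
#: daily MVPA minutes above 1080 are treated as implausible and scored 0.
STEP_MIN = 1000
STEP_MAX = 30000
MVPA_MAX = 1080

FLAG_MISSING_STEPS = "MISSING_STEPS"
FLAG_MISSING_MVPA = "MISSING_MVPA"
FLAG_IMPLAUSIBLE_STEPS = "IMPLAUSIBLE_STEPS"
FLAG_IMPLAUSIBLE_MVPA = "IMPLAUSIBLE_MVPA"

#: Column layout of the long-format daily log CSV (empty field = not submitted).
LOG_COLUMNS = ["participant_id", "week", "day", "steps", "mvpa_minutes"]

CLEAN_COLUMNS = [
    "participant_id",
    "week",
    "day",
    "steps_submitted",
    "steps_clean",
    "mvpa_submitted",
    "mvpa_clean",
    "missing_steps",
    "implausible_steps",
    "missing_mvpa",
    "implausible_mvpa",
]


@dataclass(frozen=True)
class DailyRecord:
    """One participant-day of self-reported steps and MVPA minutes.

    A metric's value is present iff that metric was submitted that day; a
    submitted value of 0 is a legitimate record (it counts as
    self-monitoring).
    """

    participant_id: str
    week: int
    day: int  # 1-7 within the program week
    steps: int | None = None
    mvpa_minutes: float | None = None

    @property
    def steps_submitted(self) -> bool:
        return self.steps is not None

    @property
    def mvpa_submitted(self) -> bool:
        return self.mvpa_minutes is not None


@dataclass(frozen=True)
class CleanDailyRecord:
    """A cleaned participant-day: zero-substituted values plus audit flags."""

    participant_id: str
    week: int
    day: int
    steps_submitted: bool
    steps_clean: int
    mvpa_submitted: bool
    mvpa_clean: float
    flags: frozenset[str] = field(default_factory=frozenset)


def clean_day(record: DailyRecord) -> CleanDailyRecord:
    """Apply the missing/implausible rules to a single day.

    Submitted in-range values pass through unchanged; submitted out-of-range
    values become 0 with an IMPLAUSIBLE flag; absent values become 0 with a
    MISSING flag. Submission booleans are never altered. Negative reported
    values are rejected as malformed (they are not covered by the cleaning
    rules).
    """
    if record.day < 1 or record.day > DAYS_PER_WEEK:
        raise MalformedRecordError(f"day index {record.day} outside 1-7")
    flags: set[str] = set()

    if record.steps is None:
        steps_clean = 0
        flags.add(FLAG_MISSING_STEPS)
    else:
        if record.steps < 0:
            raise MalformedRecordError(f"negative step count {record.steps}")
        if STEP_MIN <= record.steps <= STEP_MAX:
            steps_clean = int(record.steps)
        else:
            steps_clean = 0
            flags.add(FLAG_IMPLAUSIBLE_STEPS)

    if record.mvpa_minutes is None:
        mvpa_clean = 0.0
        flags.add(FLAG_MISSING_MVPA)
    else:
        if record.mvpa_minutes < 0:
            raise MalformedRecordError(f"negative MVPA minutes {record.mvpa_minutes}")
        if record.mvpa_minutes <= MVPA_MAX:
            mvpa_clean = float(record.mvpa_minutes)
        else:
            mvpa_clean = 0.0
            flags.add(FLAG_IMPLAUSIBLE_MVPA)

    return CleanDailyRecord(
        participant_id=record.participant_id,
        week=int(record.week),
        day=int(record.day),
        steps_submitted=record.steps_submitted,
        steps_clean=steps_clean,
        mvpa_submitted=record.mvpa_submitted,
        mvpa_clean=mvpa_clean,
        flags=frozenset(flags),
    )


def clean_logs(logs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`clean_day` over a long-format daily log DataFrame.

    Parameters
    ----------
    logs
        Columns ``participant_id, week, day, steps, mvpa_minutes``; NaN (or
        pandas NA) in a metric column means that metric was not submitted.

    Returns
    -------
    DataFrame with :data:`CLEAN_COLUMNS`, one row per input row.
    """
    missing = [c for c in LOG_COLUMNS if c not in logs.columns]
    if missing:
        raise MalformedRecordError(f"daily log is missing columns: {missing}")
    df = logs.loc[:, LOG_COLUMNS].copy()
    day = pd.to_numeric(df["day"])
    if ((day < 1) | (day > DAYS_PER_WEEK)).any():
        raise MalformedRecordError("day index outside 1-7")

    steps = pd.to_numeric(df["steps"], errors="raise")
    mvpa = pd.to_numeric(df["mvpa_minutes"], errors="raise")
    if (steps.dropna() < 0).any() or (mvpa.dropna() < 0).any():
        raise MalformedRecordError("negative reported values are malformed")

    steps_submitted = steps.notna().to_numpy()
    mvpa_submitted = mvpa.notna().to_numpy()
    steps_val = steps.fillna(0).to_numpy(dtype=float)
    mvpa_val = mvpa.fillna(0).to_numpy(dtype=float)

    implausible_steps = steps_submitted & (
        (steps_val < STEP_MIN) | (steps_val > STEP_MAX)
    )
    implausible_mvpa = mvpa_submitted & (mvpa_val > MVPA_MAX)

    out = pd.DataFrame({"participant_id": df["participant_id"].astype(str)})
    out["week"] = pd.to_numeric(df["week"]).astype(int)
    out["day"] = day.astype(int)
    out["steps_submitted"] = steps_submitted
    out["steps_clean"] = np.where(implausible_steps, 0, steps_val).astype(int)
    out["mvpa_submitted"] = mvpa_submitted
    out["mvpa_clean"] = np.where(implausible_mvpa, 0.0, mvpa_val)
    out["missing_steps"] = ~steps_submitted
    out["implausible_steps"] = implausible_steps
    out["missing_mvpa"] = ~mvpa_submitted
    out["implausible_mvpa"] = implausible_mvpa
    return out[CLEAN_COLUMNS]


def expand_to_full_grid(
    clean: pd.DataFrame,
    participants,
    weeks=GOAL_WEEKS,
) -> pd.DataFrame:
    """Complete the participant x week x day grid with all-missing rows.

    Every (participant, week, day 1-7) cell of the output exists exactly
    once; cells with no input row are missing for both metrics. Weekly
    aggregation denominators (7 days) are therefore always well defined.

    Raises
    ------
    DuplicateRecordError
        If the input contains duplicate (participant, week, day) keys.
    DataError
        If the input mentions a participant absent from ``participants``.
    """
    participants = [str(p) for p in participants]
    weeks = [int(w) for w in weeks]
    keys = ["participant_id", "week", "day"]

    dup = clean.duplicated(subset=keys, keep=False)
    if dup.any():
        offending = (
            clean.loc[dup, keys].drop_duplicates().to_records(index=False).tolist()
        )
        raise DuplicateRecordError(
            f"duplicate (participant, week, day) keys: {offending[:20]}"
        )
    unknown = set(clean["participant_id"].astype(str)) - set(participants)
    if unknown:
        raise DataError(f"records for participants absent from roster: {sorted(unknown)[:20]}")

    grid = pd.MultiIndex.from_product(
        [participants, weeks, range(1, DAYS_PER_WEEK + 1)], names=keys
    )
    body = (
        clean[clean["week"].isin(weeks)]
        .set_index(keys)
        .reindex(grid)
        .reset_index()
    )
    filled = body["steps_submitted"].notna()
    for col, default in [
        ("steps_submitted", False),
        ("mvpa_submitted", False),
        ("steps_clean", 0),
        ("mvpa_clean", 0.0),
        ("implausible_steps", False),
        ("implausible_mvpa", False),
    ]:
        body[col] = body[col].where(filled, default)
    body["missing_steps"] = ~body["steps_submitted"].astype(bool)
    body["missing_mvpa"] = ~body["mvpa_submitted"].astype(bool)
    for col in ["steps_submitted", "mvpa_submitted", "implausible_steps", "implausible_mvpa"]:
        body[col] = body[col].astype(bool)
    body["steps_clean"] = body["steps_clean"].astype(int)
    body["mvpa_clean"] = body["mvpa_clean"].astype(float)
    return body[CLEAN_COLUMNS].sort_values(keys, ignore_index=True)


def read_daily_logs(path) -> pd.DataFrame:
    """Read a long-format daily log CSV (empty field = not submitted)."""
    df = pd.read_csv(Path(path), dtype={"participant_id": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {missing}")
    return df[LOG_COLUMNS]


def write_clean_logs(clean: pd.DataFrame, path) -> None:
    clean.to_csv(Path(path), index=False)


def substitution_counts(clean: pd.DataFrame) -> dict[str, int]:
    """Counts of missing/implausible substitutions per metric (for logging)."""
    return {
        "missing_steps": int(clean["missing_steps"].sum()),
        "implausible_steps": int(clean["implausible_steps"].sum()),
        "missing_mvpa": int(clean["missing_mvpa"].sum()),
        "implausible_mvpa": int(clean["implausible_mvpa"].sum()),
    }
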