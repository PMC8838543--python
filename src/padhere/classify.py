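"""Weekly goal attainment and three-state adherence classification.

For every participant-week and each metric separately:

* steps — the weekly value is the 7-day average of cleaned daily counts
  (missing and implausible days count as 0 in the numerator and the
  denominator stays 7); the attainment proportion is
  ``100 * weekly_value / step_goal``;
* MVPA — the weekly value is the weekly total of cleaned minutes and the
  proportion is ``100 * weekly_value / mvpa_goal``.

A proportion of at least 100 means the goal was met. Combined with the
per-metric self-monitoring indicator (at least one submitted day that week)
this yields one of three mutually exclusive statuses: ADHERENT (monitored
and goal met), SUBOPTIMAL (monitored, goal unmet), NONADHERENT (not
monitored). The two metrics are classified independently: a participant may
be adherent to the minute goal and nonadherent to the step goal in the same
week.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cleaning import CLEAN_COLUMNS
from .errors import ConfigurationError, DataError
from .schedule import GoalSchedule
from .states import (
    DAYS_PER_WEEK,
    METRICS,
    STATUS_LABELS,
    Metric,
    Status,
)

WEEKLY_STATUS_COLUMNS = [
    "participant_id",
    "week",
    "metric",
    "monitored_days",
    "weekly_value",
    "goal",
    "proportion",
    "goal_met",
    "status",
]


def weekly_step_proportion(days: pd.DataFrame, goal: float) -> tuple[float, float]:
    """Weekly average daily steps and percent of the daily step goal.

    ``days`` must hold the 7 grid-expanded cleaned day rows of one
    participant-week. Missing days contribute 0 and the denominator is
    always 7.
    """
    if goal <= 0:
        raise ConfigurationError(f"step goal must be positive, got {goal}")
    if len(days) != DAYS_PER_WEEK:
        raise DataError(f"expected {DAYS_PER_WEEK} day rows, got {len(days)}")
    weekly_value = float(days["steps_clean"].sum()) / DAYS_PER_WEEK
    return weekly_value, 100.0 * weekly_value / goal


def weekly_mvpa_proportion(days: pd.DataFrame, goal: float) -> tuple[float, float]:
    """Weekly total MVPA minutes and percent of the weekly minute goal."""
    if goal <= 0:
        raise ConfigurationError(f"MVPA goal must be positive, got {goal}")
    if len(days) != DAYS_PER_WEEK:
        raise DataError(f"expected {DAYS_PER_WEEK} day rows, got {len(days)}")
    weekly_value = float(days["mvpa_clean"].sum())
    return weekly_value, 100.0 * weekly_value / goal


def classify_week(self_monitored: bool, goal_met: bool) -> Status:
    """Map the (self-monitored, goal-met) pair to the unique status.

    The combination (not monitored, goal met) cannot arise from the cleaning
    and aggregation upstream — with no submitted days every cleaned value is
    0, so the goal cannot be met. If handed such a pair directly, the
    classification assumes that a participant who did not self-monitor also
    did not meet the goal, returns NONADHERENT, and warns.
    """
    if not self_monitored:
        if goal_met:
            warnings.warn(
                "goal_met=True with self_monitored=False is unreachable from "
                "cleaned data; assuming the goal was not met (NONADHERENT)",
                stacklevel=2,
            )
        return Status.NONADHERENT
    return Status.ADHERENT if goal_met else Status.SUBOPTIMAL


def weekly_status(
    grid: pd.DataFrame,
    schedule: GoalSchedule | None = None,
    *,
    step_denominator: str = "fixed7",
    implausible_counts_as_monitoring: bool = True,
) -> pd.DataFrame:
    """Aggregate a grid-expanded clean log into tidy weekly statuses.

    Parameters
    ----------
    grid
        Output of :func:`padhere.cleaning.expand_to_full_grid` (7 rows per
        participant-week).
    schedule
        Goal schedule; defaults to the built-in program ladder.
    step_denominator
        ``"fixed7"`` (default) divides the weekly step sum by 7;
        ``"monitored"`` divides by the number of monitored days instead — a
        sensitivity-analysis alternative, not the primary definition.
    implausible_counts_as_monitoring
        When True (default) a submitted-but-implausible entry still counts
        toward self-monitoring; False restricts monitoring credit to
        plausible submissions (sensitivity analysis).

    Returns
    -------
    Tidy DataFrame with :data:`WEEKLY_STATUS_COLUMNS`, two rows (one per
    metric) per participant-week.
    """
    if step_denominator not in ("fixed7", "monitored"):
        raise ConfigurationError(f"unknown step_denominator {step_denominator!r}")
    missing = [c for c in CLEAN_COLUMNS if c not in grid.columns]
    if missing:
        raise DataError(f"grid is missing columns {missing}")
    schedule = schedule or GoalSchedule.default()

    counts = grid.groupby(["participant_id", "week"], sort=True).size()
    if (counts != DAYS_PER_WEEK).any():
        bad = counts[counts != DAYS_PER_WEEK].index.tolist()[:10]
        raise DataError(
            f"grid must hold exactly 7 day rows per participant-week; bad keys {bad}"
        )

    frames = []
    for metric in METRICS:
        sub_col = "steps_submitted" if metric is Metric.STEPS else "mvpa_submitted"
        val_col = "steps_clean" if metric is Metric.STEPS else "mvpa_clean"
        imp_col = "implausible_steps" if metric is Metric.STEPS else "implausible_mvpa"
        work = grid[["participant_id", "week", sub_col, val_col, imp_col]].copy()
        if implausible_counts_as_monitoring:
            work["monitored"] = work[sub_col]
        else:
            work["monitored"] = work[sub_col] & ~work[imp_col]
        agg = (
            work.groupby(["participant_id", "week"], sort=True)
            .agg(monitored_days=("monitored", "sum"), value_sum=(val_col, "sum"))
            .reset_index()
        )
        agg["metric"] = metric.value
        agg["goal"] = agg["week"].map(lambda w: schedule.goal(w, metric))
        if metric is Metric.STEPS:
            if step_denominator == "fixed7":
                agg["weekly_value"] = agg["value_sum"] / DAYS_PER_WEEK
            else:
                denom = agg["monitored_days"].replace(0, np.nan)
                agg["weekly_value"] = (agg["value_sum"] / denom).fillna(0.0)
        else:
            agg["weekly_value"] = agg["value_sum"].astype(float)
        agg["proportion"] = 100.0 * agg["weekly_value"] / agg["goal"]
        agg["goal_met"] = agg["proportion"] >= 100.0
        monitored = agg["monitored_days"] >= 1
        status_code = np.where(
            ~monitored,
            Status.NONADHERENT,
            np.where(agg["goal_met"], Status.ADHERENT, Status.SUBOPTIMAL),
        )
        agg["status"] = pd.Categorical(
            [Status(c).label for c in status_code],
            categories=list(STATUS_LABELS),
            ordered=True,
        )
        frames.append(agg[WEEKLY_STATUS_COLUMNS])

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["participant_id", "week", "metric"], ignore_index=True
    )


def build_state_sequences(weekly: pd.DataFrame, metric: Metric) -> pd.DataFrame:
    """Pivot weekly statuses to a participant x week matrix of status codes.

    Returns a DataFrame indexed by participant_id with one integer column
    per scheduled week (0 = nonadherent, 1 = suboptimal, 2 = adherent).
    Sequences must be complete: any gap raises :class:`DataError`.
    """
    metric = Metric(metric)
    sub = weekly[weekly["metric"] == metric.value]
    if sub.empty:
        raise DataError(f"no weekly rows for metric {metric.value!r}")
    codes = sub.assign(
        code=sub["status"].astype(str).map({s.label: int(s) for s in Status})
    )
    mat = codes.pivot(index="participant_id", columns="week", values="code")
    if mat.isna().any().any():
        holes = mat.isna().stack()
        keys = holes[holes].index.tolist()[:10]
        raise DataError(f"incomplete status sequences; missing cells {keys}")
    mat = mat[sorted(mat.columns)].astype(np.int8)
    mat.columns.name = "week"
    return mat
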