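"""Week-indexed physical-activity goal schedule.

The program prescribes concurrent step and MVPA-minute goals from week 3
through week 24. During the graded phase (weeks 3-8) goals ramp up stepwise
(7000 to 10,000 steps/day; 50 to 150 MVPA minutes/week); during the fixed
phase (weeks 9-24) they are constant at 10,000 steps/day and 200 MVPA
minutes/week. Weeks 1-2 carry no goal: requesting a goal there raises
:class:`~padhere.errors.OutOfScheduleError` rather than returning 0, so
unprescribed weeks can never be silently misclassified.

Alternative goal ladders (other programs use different MVPA doses) can be
loaded from a YAML/JSON-style list of row dicts via
:meth:`GoalSchedule.from_config`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError, OutOfScheduleError
from .states import FIRST_GOAL_WEEK, GOAL_WEEKS, LAST_GOAL_WEEK, Metric, Phase


@dataclass(frozen=True)
class WeekGoals:
    """Goals in force for a single program week."""

    week: int
    step_goal: int  # steps/day
    mvpa_goal: int  # minutes/week
    phase: Phase


# Default ladder: (first week, last week, steps/day, MVPA minutes/week, phase).
_DEFAULT_ROWS: tuple[tuple[int, int, int, int, Phase], ...] = (
    (3, 3, 7000, 50, Phase.GRADED),
    (4, 4, 8000, 50, Phase.GRADED),
    (5, 5, 8000, 100, Phase.GRADED),
    (6, 6, 9000, 100, Phase.GRADED),
    (7, 7, 9000, 150, Phase.GRADED),
    (8, 8, 10000, 150, Phase.GRADED),
    (9, 24, 10000, 200, Phase.FIXED),
)


@dataclass(frozen=True)
class GoalSchedule:
    """Mapping from program week (3-24) to the prescribed goals and phase.

    Invariants checked at construction: the schedule covers every week 3-24
    exactly once, both goals are non-decreasing in week, and the phase is
    GRADED for weeks 3-8 and FIXED for weeks 9-24 (custom schedules may move
    the phase boundary but must keep phases contiguous).
    """

    entries: dict[int, WeekGoals] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            object.__setattr__(self, "entries", _default_entries())
        weeks = sorted(self.entries)
        if weeks != list(GOAL_WEEKS):
            raise ConfigurationError(
                f"schedule must cover weeks {FIRST_GOAL_WEEK}-{LAST_GOAL_WEEK} "
                f"exactly once; got weeks {weeks}"
            )
        prev: WeekGoals | None = None
        seen_fixed = False
        for week in weeks:
            wg = self.entries[week]
            if wg.week != week:
                raise ConfigurationError(f"entry keyed {week} carries week {wg.week}")
            if wg.step_goal <= 0 or wg.mvpa_goal <= 0:
                raise ConfigurationError(f"non-positive goal at week {week}")
            if prev is not None:
                if wg.step_goal < prev.step_goal or wg.mvpa_goal < prev.mvpa_goal:
                    raise ConfigurationError(
                        f"goals must be non-decreasing; week {week} decreases"
                    )
            if wg.phase is Phase.FIXED:
                seen_fixed = True
            elif wg.phase is Phase.GRADED and seen_fixed:
                raise ConfigurationError("GRADED week after FIXED week")
            else:
                if wg.phase not in (Phase.GRADED, Phase.FIXED):
                    raise ConfigurationError(f"invalid phase {wg.phase!r}")
            prev = wg

    # -- lookups ---------------------------------------------------------

    def _entry(self, week: int) -> WeekGoals:
        try:
            return self.entries[int(week)]
        except KeyError:
            raise OutOfScheduleError(
                f"no physical-activity goal is prescribed for week {week}; "
                f"goals run from week {FIRST_GOAL_WEEK} to {LAST_GOAL_WEEK}"
            ) from None

    def step_goal(self, week: int) -> int:
        """Daily step goal (steps/day) in force at ``week``."""
        return self._entry(week).step_goal

    def mvpa_goal(self, week: int) -> int:
        """Weekly MVPA goal (minutes/week) in force at ``week``."""
        return self._entry(week).mvpa_goal

    def goal(self, week: int, metric: Metric) -> int:
        """The goal for ``metric`` at ``week`` in that metric's native units."""
        if Metric(metric) is Metric.STEPS:
            return self.step_goal(week)
        return self.mvpa_goal(week)

    def phase_of(self, week: int) -> Phase:
        """GRADED for the ramp-up weeks, FIXED thereafter."""
        return self._entry(week).phase

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    def phase_weeks(self, phase: Phase) -> tuple[int, ...]:
        """Weeks belonging to ``phase`` (FULL means every scheduled week)."""
        phase = Phase(phase)
        if phase is Phase.FULL:
            return self.weeks
        return tuple(w for w in self.weeks if self.entries[w].phase is phase)

    # -- construction ----------------------------------------------------

    @classmethod
    def default(cls) -> "GoalSchedule":
        return cls()

    @classmethod
    def from_rows(cls, rows) -> "GoalSchedule":
        """Build from dicts with keys week_start, week_end, step_goal, mvpa_goal, phase."""
        entries: dict[int, WeekGoals] = {}
        for row in rows:
            try:
                start, end = int(row["week_start"]), int(row["week_end"])
                step, mvpa = int(row["step_goal"]), int(row["mvpa_goal"])
                phase = Phase(str(row["phase"]).lower())
            except (KeyError, ValueError) as exc:
                raise ConfigurationError(f"bad schedule row {row!r}: {exc}") from exc
            for week in range(start, end + 1):
                if week in entries:
                    raise ConfigurationError(f"week {week} defined twice")
                entries[week] = WeekGoals(week, step, mvpa, phase)
        return cls(entries)

    @classmethod
    def from_config(cls, path) -> "GoalSchedule":
        """Load a schedule from a YAML or JSON file holding a list of rows."""
        text = Path(path).read_text()
        rows = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        if not isinstance(rows, list):
            raise ConfigurationError("schedule config must be a list of rows")
        return cls.from_rows(rows)

    def to_rows(self) -> list[dict]:
        """Serialize to the row-dict form accepted by :meth:`from_rows`."""
        rows: list[dict] = []
        for week in self.weeks:
            wg = self.entries[week]
            if rows and (
                rows[-1]["step_goal"] == wg.step_goal
                and rows[-1]["mvpa_goal"] == wg.mvpa_goal
                and rows[-1]["phase"] == wg.phase.value
            ):
                rows[-1]["week_end"] = week
            else:
                rows.append(
                    {
                        "week_start": week,
                        "week_end": week,
                        "step_goal": wg.step_goal,
                        "mvpa_goal": wg.mvpa_goal,
                        "phase": wg.phase.value,
                    }
                )
        return rows


def _default_entries() -> dict[int, WeekGoals]:
    entries: dict[int, WeekGoals] = {}
    for start, end, step, mvpa, phase in _DEFAULT_ROWS:
        for week in range(start, end + 1):
            entries[week] = WeekGoals(week, step, mvpa, phase)
    return entries
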