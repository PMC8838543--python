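"""Core categorical vocabulary for the adherence pipeline.

Each participant-week-metric is assigned exactly one of three mutually
exclusive adherence statuses:

* ``NONADHERENT`` — no self-monitoring record submitted that week;
* ``SUBOPTIMAL`` — at least one record submitted but the weekly goal unmet;
* ``ADHERENT`` — at least one record submitted and the weekly goal met.

The integer coding orders statuses from least to most adherent, which is
also the row/column order used in reported transition tables (nonadherent,
suboptimally adherent, adherent).
"""

from __future__ import annotations

import enum


class Status(enum.IntEnum):
    """Weekly adherence status, ordered NONADHERENT < SUBOPTIMAL < ADHERENT."""

    NONADHERENT = 0
    SUBOPTIMAL = 1
    ADHERENT = 2

    @property
    def label(self) -> str:
        return _STATUS_LABELS[self]


_STATUS_LABELS = {
    Status.NONADHERENT: "nonadherent",
    Status.SUBOPTIMAL: "suboptimal",
    Status.ADHERENT: "adherent",
}

#: Display order used in all tabular output.
STATUS_ORDER: tuple[Status, ...] = (
    Status.NONADHERENT,
    Status.SUBOPTIMAL,
    Status.ADHERENT,
)

STATUS_LABELS: tuple[str, ...] = tuple(s.label for s in STATUS_ORDER)


class Metric(str, enum.Enum):
    """The two self-monitored physical-activity metrics.

    ``STEPS`` carries a daily step goal (weekly attainment is judged on the
    7-day average); ``MVPA`` carries a weekly minutes goal for
    moderate-to-vigorous physical activity (judged on the weekly total).
    """

    STEPS = "steps"
    MVPA = "mvpa"


METRICS: tuple[Metric, ...] = (Metric.STEPS, Metric.MVPA)


class Phase(str, enum.Enum):
    """Program goal phase.

    The graded phase (weeks 3-8) ramps goals up stepwise; the fixed phase
    (weeks 9-24) holds them constant. ``FULL`` denotes the pooled analysis
    window, weeks 3-24.
    """

    GRADED = "graded"
    FIXED = "fixed"
    FULL = "full"


#: Analysis week windows by phase (inclusive endpoints).
PHASE_WEEKS: dict[Phase, tuple[int, int]] = {
    Phase.GRADED: (3, 8),
    Phase.FIXED: (9, 24),
    Phase.FULL: (3, 24),
}

FIRST_GOAL_WEEK = 3
LAST_GOAL_WEEK = 24
GOAL_WEEKS: tuple[int, ...] = tuple(range(FIRST_GOAL_WEEK, LAST_GOAL_WEEK + 1))
N_GOAL_WEEKS = len(GOAL_WEEKS)  # 22
DAYS_PER_WEEK = 7


def status_from_label(label: str) -> Status:
    """Parse a status label such as ``"suboptimal"`` back into a Status."""
    for status in STATUS_ORDER:
        if status.label == label:
            return status
    raise ValueError(f"unknown adherence status label: {label!r}")


def metric_from_label(label: str) -> Metric:
    try:
        return Metric(label.lower())
    except ValueError:
        raise ValueError(f"unknown metric label: {label!r}") from None
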