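"""Synthetic cohort generator for daily self-monitoring logs.

The raw logs of the source trial are not public, so this module generates a
cohort whose *latent* weekly adherence states follow configurable
first-order Markov dynamics, then emits daily records consistent with each
week's state:

* NONADHERENT week — no record of that metric is submitted;
* SUBOPTIMAL week — at least one day submitted, weekly aggregate strictly
  below that week's goal after cleaning;
* ADHERENT week — at least one day submitted, weekly aggregate at or above
  the goal after cleaning.

With contamination disabled the emission is *classification-faithful*:
running the cleaning + weekly-classification pipeline on the emitted logs
recovers the latent states exactly, which makes the generator a parameter-
recovery oracle for the transition and regression estimators. Contaminated
days carry implausible values (cleaned to 0) but still count as submitted,
so contamination can demote goal attainment but never self-monitoring.

Defaults reproduce the study conditions of a 212-participant, 22-week
(weeks 3-24) online behavioral weight-loss program: published week-3 status
distributions, published graded-phase weekly transition matrices, and a
slowly-decaying fixed-phase matrix (the source reports no weekly
fixed-phase matrices; see docs/methods.md).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .cleaning import MVPA_MAX, STEP_MAX, STEP_MIN
from .errors import ConfigurationError
from .schedule import GoalSchedule
from .states import DAYS_PER_WEEK, GOAL_WEEKS, METRICS, Metric, Status

logger = logging.getLogger(__name__)

_ATOL = 1e-9

#: Default fixed-phase weekly transition matrix (rows/cols N, S, A): slow
#: attrition out of monitoring with nonadherence nearly absorbing.
DEFAULT_FIXED_WEEKLY = np.array(
    [
        [0.98, 0.02, 0.00],
        [0.06, 0.90, 0.04],
        [0.02, 0.14, 0.84],
    ]
)


def default_transition_matrices(
    metric: Metric, weeks=GOAL_WEEKS
) -> dict[tuple[int, int], np.ndarray]:
    """Weekly matrices keyed by consecutive (earlier, later) week pairs.

    Graded-phase pairs use the published weekly matrices; later pairs use
    :data:`DEFAULT_FIXED_WEEKLY`.
    """
    metric = Metric(metric)
    graded = reference.GRADED_WEEKLY_TRANSITIONS[metric]
    weeks = sorted(int(w) for w in weeks)
    out: dict[tuple[int, int], np.ndarray] = {}
    for lo, hi in zip(weeks[:-1], weeks[1:]):
        out[(lo, hi)] = graded.get(hi, DEFAULT_FIXED_WEEKLY).copy()
    return out


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Attributes
    ----------
    n_participants
        Cohort size (default 212, the reference cohort).
    seed
        Seed for all randomness; identical config + seed gives
        byte-identical logs.
    weeks
        Latent-state weeks, default 3-24 (22 weeks).
    initial_distribution
        Per-metric probability triple over (nonadherent, suboptimal,
        adherent) at the first week; defaults to the reference week-3
        distributions.
    transition_matrices
        Per-metric map from consecutive week pairs to 3x3 row-stochastic
        matrices; defaults per :func:`default_transition_matrices`.
    monitored_days_probs
        Distribution of the number of monitored days (1-7) in a monitored
        week; default uniform.
    under_goal_fraction_range
        Weekly aggregate of a suboptimal week, as a fraction of goal
        (subset of (0, 1)).
    over_goal_fraction_range
        Weekly aggregate of an adherent week, as a fraction of goal (>= 1).
    contamination_rate
        Probability a submitted day carries an implausible value.
    dropout_hazard
        Per-week probability of permanent absorption into NONADHERENT,
        applied on top of the transition matrices (default 0: the matrices
        alone carry the dynamics).
    couple_monitoring
        If True, both metrics share one monitored-day set in weeks where
        both are monitored (cross-metric coupling); default False
        (metrics independent).
    """

    n_participants: int = reference.N_PARTICIPANTS
    seed: int = 0
    weeks: tuple[int, ...] = tuple(GOAL_WEEKS)
    initial_distribution: dict[Metric, np.ndarray] = field(default_factory=dict)
    transition_matrices: dict[Metric, dict[tuple[int, int], np.ndarray]] = field(
        default_factory=dict
    )
    monitored_days_probs: np.ndarray = field(
        default_factory=lambda: np.full(DAYS_PER_WEEK, 1.0 / DAYS_PER_WEEK)
    )
    under_goal_fraction_range: tuple[float, float] = (0.15, 0.9)
    over_goal_fraction_range: tuple[float, float] = (1.0, 1.3)
    contamination_rate: float = 0.0
    dropout_hazard: float = 0.0
    couple_monitoring: bool = False

    def __post_init__(self) -> None:
        self.weeks = tuple(sorted(int(w) for w in self.weeks))
        if len(self.weeks) < 1:
            raise ConfigurationError("at least one week is required")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if not self.initial_distribution:
            self.initial_distribution = {
                m: reference.initial_distribution(m) for m in METRICS
            }
        if not self.transition_matrices:
            self.transition_matrices = {
                m: default_transition_matrices(m, self.weeks) for m in METRICS
            }
        self.monitored_days_probs = np.asarray(self.monitored_days_probs, dtype=float)
        self.validate()

    def validate(self) -> None:
        for metric in METRICS:
            dist = np.asarray(self.initial_distribution[metric], dtype=float)
            if dist.shape != (3,) or (dist < 0).any() or abs(dist.sum() - 1) > _ATOL:
                raise ConfigurationError(
                    f"initial distribution for {metric.value} must be a "
                    "non-negative triple summing to 1"
                )
            self.initial_distribution[metric] = dist
            mats = self.transition_matrices[metric]
            for lo, hi in zip(self.weeks[:-1], self.weeks[1:]):
                if (lo, hi) not in mats:
                    raise ConfigurationError(
                        f"missing transition matrix for {metric.value} "
                        f"weeks {lo}->{hi}"
                    )
            for pair, mat in mats.items():
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (3, 3) or (mat < 0).any():
                    raise ConfigurationError(
                        f"{metric.value} {pair}: matrix must be 3x3 non-negative"
                    )
                if np.abs(mat.sum(axis=1) - 1).max() > _ATOL:
                    raise ConfigurationError(
                        f"{metric.value} {pair}: rows must sum to 1 within 1e-9"
                    )
                mats[pair] = mat
        p = self.monitored_days_probs
        if p.shape != (DAYS_PER_WEEK,) or (p < 0).any() or abs(p.sum() - 1) > _ATOL:
            raise ConfigurationError(
                "monitored_days_probs must be 7 non-negative values summing to 1"
            )
        lo, hi = self.under_goal_fraction_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("under_goal_fraction_range must be within (0, 1)")
        lo, hi = self.over_goal_fraction_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("over_goal_fraction_range must be >= 1")
        if not 0 <= self.contamination_rate <= 1:
            raise ConfigurationError("contamination_rate must be in [0, 1]")
        if not 0 <= self.dropout_hazard <= 1:
            raise ConfigurationError("dropout_hazard must be in [0, 1]")

    def provenance(self) -> dict:
        """JSON-serializable record of every generative parameter."""
        return {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "weeks": list(self.weeks),
            "initial_distribution": {
                m.value: self.initial_distribution[m].tolist() for m in METRICS
            },
            "transition_matrices": {
                m.value: {
                    f"{lo}->{hi}": mat.tolist()
                    for (lo, hi), mat in sorted(self.transition_matrices[m].items())
                }
                for m in METRICS
            },
            "monitored_days_probs": self.monitored_days_probs.tolist(),
            "under_goal_fraction_range": list(self.under_goal_fraction_range),
            "over_goal_fraction_range": list(self.over_goal_fraction_range),
            "contamination_rate": self.contamination_rate,
            "dropout_hazard": self.dropout_hazard,
            "couple_monitoring": self.couple_monitoring,
        }


def simulate_states(config: SimulationConfig) -> dict[Metric, np.ndarray]:
    """Draw latent weekly state sequences for every participant and metric.

    Returns a map metric -> int8 array of shape (n_participants, n_weeks)
    with entries 0/1/2 (nonadherent/suboptimal/adherent). States start from
    the initial distribution and chain through the weekly matrices;
    ``dropout_hazard`` additionally absorbs participants into NONADHERENT
    permanently. Reproducible given the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n, weeks = config.n_participants, config.weeks
    out: dict[Metric, np.ndarray] = {}
    for metric in METRICS:
        states = np.empty((n, len(weeks)), dtype=np.int8)
        states[:, 0] = rng.choice(3, size=n, p=config.initial_distribution[metric])
        dropped = np.zeros(n, dtype=bool)
        for k, (lo, hi) in enumerate(zip(weeks[:-1], weeks[1:]), start=1):
            mat = config.transition_matrices[metric][(lo, hi)]
            # Inverse-CDF draw per current state keeps one uniform per cell.
            u = rng.random(n)
            cum = np.cumsum(mat, axis=1)
            prev = states[:, k - 1].astype(np.intp)
            states[:, k] = (u[:, None] > cum[prev]).sum(axis=1)
            if config.dropout_hazard > 0:
                dropped |= rng.random(n) < config.dropout_hazard
                states[dropped, k] = int(Status.NONADHERENT)
        out[metric] = states
    return out


# ---------------------------------------------------------------------------
# emission helpers


def _bounded_split(total: int, k: int, low: int, high: int, rng) -> np.ndarray:
    """Split ``total`` into ``k`` integers in [low, high] summing exactly.

    Requires k*low <= total <= k*high. Starts from a symmetric-Dirichlet
    (multinomial) allocation of the slack above ``low`` and repairs any
    values pushed past ``high`` by redistributing the excess to days with
    headroom.
    """
    if not k * low <= total <= k * high:
        raise ValueError(f"cannot split {total} into {k} values in [{low}, {high}]")
    weights = rng.dirichlet(np.full(k, 2.0))
    vals = low + rng.multinomial(total - k * low, weights)
    while True:
        over = vals > high
        if not over.any():
            break
        excess = int((vals[over] - high).sum())
        vals[over] = high
        room = np.flatnonzero(vals < high)
        share = rng.multinomial(excess, np.full(len(room), 1.0 / len(room)))
        vals[room] += share  # may overshoot again; loop repairs
    return vals


def _weekly_total(state: int, goal_total: int, config: SimulationConfig, rng) -> int:
    """Target weekly aggregate (before any contamination) for a monitored week."""
    if state == int(Status.ADHERENT):
        lo, hi = config.over_goal_fraction_range
        total = math.ceil(rng.uniform(lo, hi) * goal_total)
        return max(total, goal_total)
    lo, hi = config.under_goal_fraction_range
    total = round(rng.uniform(lo, hi) * goal_total)
    return int(min(max(total, 1), goal_total - 1))


def _emit_step_week(
    state: int, goal: int, days: np.ndarray, config: SimulationConfig, rng
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Day values for one monitored step week.

    Returns (values, possibly-extended day set, whether the day set had to
    grow). An adherent week whose target total exceeds the plausibility
    capacity of the drawn monitored days (STEP_MAX per day) cannot be
    emitted faithfully, so the day set is extended to the minimum feasible
    size; a suboptimal target is simply capped at the day capacity, which
    keeps the week suboptimal.
    """
    goal_total = goal * DAYS_PER_WEEK
    total = _weekly_total(state, goal_total, config, rng)
    d = len(days)
    adjusted = False
    if state == int(Status.ADHERENT):
        d_min = math.ceil(total / STEP_MAX)
        if d < d_min:
            days = _grow_days(days, d_min, rng)
            d = d_min
            adjusted = True
        vals = _bounded_split(total, d, STEP_MIN, STEP_MAX, rng)
    else:
        # Suboptimal: nonzero days must be plausible; leftovers are
        # submitted zero-reports (still self-monitoring).
        total = min(total, d * STEP_MAX)
        k_max = total // STEP_MIN
        if k_max == 0:
            vals = np.zeros(d, dtype=int)
            vals[0] = total  # below 1000; cleans to 0, week stays suboptimal
        else:
            k = int(min(d, k_max))
            k = max(k, math.ceil(total / STEP_MAX))
            vals = np.zeros(d, dtype=int)
            vals[:k] = _bounded_split(total, k, STEP_MIN, STEP_MAX, rng)
            rng.shuffle(vals)
    return vals, days, adjusted


def _emit_mvpa_week(
    state: int, goal: int, days: np.ndarray, config: SimulationConfig, rng
) -> np.ndarray:
    """Day values for one monitored MVPA week (weekly-total goal)."""
    total = _weekly_total(state, goal, config, rng)
    d = len(days)
    high = min(MVPA_MAX, total)
    vals = _bounded_split(total, d, 0, max(high, math.ceil(total / d)), rng)
    return vals


def _grow_days(days: np.ndarray, k: int, rng) -> np.ndarray:
    """Extend a monitored-day set to k days, keeping the originals."""
    pool = np.setdiff1d(np.arange(1, DAYS_PER_WEEK + 1), days)
    extra = rng.choice(pool, size=k - len(days), replace=False)
    return np.sort(np.concatenate([days, extra]))


def _contaminate(metric: Metric, rng) -> int:
    if metric is Metric.STEPS:
        # Implausible on either side of the [1000, 30000] band.
        if rng.random() < 0.5:
            return int(rng.integers(1, STEP_MIN))
        return int(rng.integers(STEP_MAX + 1, STEP_MAX + 20001))
    return int(rng.integers(MVPA_MAX + 1, MVPA_MAX + 921))


def emit_daily_logs(
    states: dict[Metric, np.ndarray],
    config: SimulationConfig,
    schedule: GoalSchedule | None = None,
) -> pd.DataFrame:
    """Emit long-format daily records consistent with the latent states.

    Returns a DataFrame with columns ``participant_id, week, day, steps,
    mvpa_minutes``; NaN marks a metric not submitted that day. Only days
    with at least one submitted metric appear.
    """
    schedule = schedule or GoalSchedule.default()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, weeks = config.n_participants, config.weeks
    id_width = max(4, len(str(n - 1)))
    pids = [f"p{idx:0{id_width}d}" for idx in range(n)]

    rows_pid: list[str] = []
    rows_week: list[int] = []
    rows_day: list[int] = []
    rows_steps: list[float] = []
    rows_mvpa: list[float] = []
    n_day_adjustments = 0

    for i, pid in enumerate(pids):
        for k, week in enumerate(weeks):
            day_vals: dict[int, dict[Metric, float]] = {}
            shared_days: np.ndarray | None = None
            for metric in METRICS:
                state = int(states[metric][i, k])
                if state == int(Status.NONADHERENT):
                    continue
                n_days = int(rng.choice(DAYS_PER_WEEK, p=config.monitored_days_probs)) + 1
                if config.couple_monitoring and shared_days is not None:
                    days = shared_days[: min(n_days, len(shared_days))]
                    if len(days) < 1:
                        days = shared_days[:1]
                    days = np.sort(days)
                else:
                    days = np.sort(
                        rng.choice(
                            np.arange(1, DAYS_PER_WEEK + 1), size=n_days, replace=False
                        )
                    )
                if config.couple_monitoring and shared_days is None:
                    shared_days = days
                goal = schedule.goal(week, metric)
                if metric is Metric.STEPS:
                    vals, days, adjusted = _emit_step_week(state, goal, days, config, rng)
                    n_day_adjustments += adjusted
                else:
                    vals = _emit_mvpa_week(state, goal, days, config, rng)
                for day, val in zip(days, vals):
                    val = float(val)
                    if config.contamination_rate > 0 and (
                        rng.random() < config.contamination_rate
                    ):
                        val = float(_contaminate(metric, rng))
                    day_vals.setdefault(int(day), {})[metric] = val
            for day in sorted(day_vals):
                rows_pid.append(pid)
                rows_week.append(int(week))
                rows_day.append(day)
                rows_steps.append(day_vals[day].get(Metric.STEPS, np.nan))
                rows_mvpa.append(day_vals[day].get(Metric.MVPA, np.nan))

    if n_day_adjustments:
        logger.warning(
            "extended monitored-day sets upward for %d adherent step weeks "
            "whose target totals exceeded the plausibility capacity of the "
            "drawn days",
            n_day_adjustments,
        )
    return pd.DataFrame(
        {
            "participant_id": rows_pid,
            "week": rows_week,
            "day": rows_day,
            "steps": rows_steps,
            "mvpa_minutes": rows_mvpa,
        }
    )


def participant_ids(config: SimulationConfig) -> list[str]:
    """The roster of ids :func:`emit_daily_logs` uses, in order."""
    id_width = max(4, len(str(config.n_participants - 1)))
    return [f"p{idx:0{id_width}d}" for idx in range(config.n_participants)]


def simulate_cohort(
    config: SimulationConfig, schedule: GoalSchedule | None = None
) -> tuple[dict[Metric, np.ndarray], pd.DataFrame]:
    """Convenience wrapper: latent states plus emitted daily logs."""
    states = simulate_states(config)
    logs = emit_daily_logs(states, config, schedule)
    return states, logs


def write_logs(logs: pd.DataFrame, path, config: SimulationConfig | None = None) -> None:
    """Write daily logs as CSV (empty field = not submitted); sidecar JSON
    records the generative configuration when given."""
    path = Path(path)
    out = logs.copy()
    out["steps"] = out["steps"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["mvpa_minutes"] = out["mvpa_minutes"].map(
        lambda v: "" if pd.isna(v) else format(float(v), "g")
    )
    out.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(config.provenance(), indent=2, sort_keys=True))
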