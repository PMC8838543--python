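import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from padhere import classify, cleaning
from padhere.errors import ConfigurationError
from padhere.schedule import GoalSchedule
from padhere.states import Metric, Status

SCHEDULE = GoalSchedule.default()


def _grid_from_raw(rows, participants, weeks):
    clean = cleaning.clean_logs(pd.DataFrame(rows, columns=cleaning.LOG_COLUMNS))
    return cleaning.expand_to_full_grid(clean, participants, weeks)


def _day(pid, week, day, steps=None, mvpa=None):
    return {
        "participant_id": pid,
        "week": week,
        "day": day,
        "steps": steps,
        "mvpa_minutes": mvpa,
    }


# ---------------------------------------------------------------------------
# weekly proportions


def test_step_proportion_boundary_goal_met():
    rows = [_day("p1", 8, d, steps=10000) for d in range(1, 8)]
    grid = _grid_from_raw(rows, ["p1"], [8])
    value, prop = classify.weekly_step_proportion(grid, SCHEDULE.step_goal(8))
    assert value == 10000 and prop == 100.0


def test_step_proportion_missing_days_keep_denominator_seven():
    rows = [_day("p1", 3, d, steps=7000) for d in range(1, 5)]
    grid = _grid_from_raw(rows, ["p1"], [3])
    value, prop = classify.weekly_step_proportion(grid, SCHEDULE.step_goal(3))
    assert value == pytest.approx(28000 / 7)
    assert prop == pytest.approx(100 * 4000 / 7000)


def test_all_missing_week_scores_zero():
    grid = _grid_from_raw([], ["p1"], [3])
    value, prop = classify.weekly_step_proportion(grid, 7000)
    assert (value, prop) == (0.0, 0.0)


@pytest.mark.parametrize(
    "minutes, goal, expect_prop, expect_met",
    [(50, 50, 100.0, True), (49, 50, 98.0, False), (200, 200, 100.0, True)],
)
def test_mvpa_proportion_boundaries(minutes, goal, expect_prop, expect_met):
    rows = [_day("p1", 3, 1, mvpa=minutes)]
    grid = _grid_from_raw(rows, ["p1"], [3])
    value, prop = classify.weekly_mvpa_proportion(grid, goal)
    assert value == minutes and prop == pytest.approx(expect_prop)
    assert (prop >= 100) is expect_met


def test_nonpositive_goal_rejected():
    grid = _grid_from_raw([], ["p1"], [3])
    with pytest.raises(ConfigurationError):
        classify.weekly_step_proportion(grid, 0)
    with pytest.raises(ConfigurationError):
        classify.weekly_mvpa_proportion(grid, -50)


# ---------------------------------------------------------------------------
# the 3-state rule


@pytest.mark.parametrize(
    "monitored, met, expected",
    [
        (True, True, Status.ADHERENT),
        (True, False, Status.SUBOPTIMAL),
        (False, False, Status.NONADHERENT),
    ],
)
def test_classify_week_table(monitored, met, expected):
    assert classify.classify_week(monitored, met) is expected


def test_unreachable_pair_maps_to_nonadherent_with_warning():
    with pytest.warns(UserWarning, match="was not met"):
        assert classify.classify_week(False, True) is Status.NONADHERENT


# ---------------------------------------------------------------------------
# independent brute-force oracle on enumerated micro-cohorts


def _oracle_status(day_values, metric, week):
    """Literal re-derivation of the weekly category from raw day values.

    Independent of the package implementation: hard-coded goal ladder,
    explicit plausibility filtering, explicit averaging rule.
    """
    step_goal = {3: 7000, 4: 8000, 5: 8000, 6: 9000, 7: 9000}.get(week, 10000)
    mvpa_goal = {3: 50, 4: 50, 5: 100, 6: 100, 7: 150, 8: 150}.get(week, 200)
    submitted = [v for v in day_values if v is not None]
    if len(submitted) == 0:
        return Status.NONADHERENT
    if metric == "steps":
        cleaned = [v if 1000 <= v <= 30000 else 0 for v in submitted]
        weekly = sum(cleaned) / 7
        met = weekly / step_goal >= 1.0
    else:
        cleaned = [v if v <= 1080 else 0 for v in submitted]
        met = sum(cleaned) / mvpa_goal >= 1.0
    return Status.ADHERENT if met else Status.SUBOPTIMAL


def test_classification_matches_brute_force_oracle():
    """Enumerated micro-cohorts agree cell-by-cell with the literal oracle."""
    day_menu = [None, 0, 800, 7000, 30000, 31000]
    mvpa_menu = [None, 0, 25, 60, 1200]
    weeks = [3, 8, 24]
    rows, expected = [], {}
    pids = []
    combos = itertools.islice(
        itertools.product(day_menu, day_menu, mvpa_menu), 0, None
    )
    for idx, (s1, s2, m1) in enumerate(combos):
        pid = f"c{idx:03d}"
        pids.append(pid)
        for week in weeks:
            steps_days = [s1, s2] + [None] * 5
            mvpa_days = [m1] + [None] * 6
            for day in range(1, 8):
                st_v, mv_v = steps_days[day - 1], mvpa_days[day - 1]
                if st_v is not None or mv_v is not None:
                    rows.append(_day(pid, week, day, steps=st_v, mvpa=mv_v))
            expected[(pid, week, "steps")] = _oracle_status(steps_days, "steps", week)
            expected[(pid, week, "mvpa")] = _oracle_status(mvpa_days, "mvpa", week)

    grid = _grid_from_raw(rows, pids, weeks)
    weekly = classify.weekly_status(grid)
    assert len(weekly) == len(pids) * len(weeks) * 2
    for _, row in weekly.iterrows():
        want = expected[(row["participant_id"], row["week"], row["metric"])]
        assert str(row["status"]) == want.label, (
            row["participant_id"],
            row["week"],
            row["metric"],
        )


# ---------------------------------------------------------------------------
# invariants


def test_statuses_exhaustive_and_exclusive(small_weekly):
    counts = small_weekly.groupby(["participant_id", "week", "metric"]).size()
    assert (counts == 1).all()
    assert set(small_weekly["status"].astype(str)) <= {
        "nonadherent",
        "suboptimal",
        "adherent",
    }
    # status consistency with its defining fields
    monitored = small_weekly["monitored_days"] >= 1
    met = small_weekly["goal_met"]
    label = small_weekly["status"].astype(str)
    assert ((label == "nonadherent") == ~monitored).all()
    assert ((label == "adherent") == (monitored & met)).all()
    assert ((label == "suboptimal") == (monitored & ~met)).all()


@given(
    steps=st.lists(st.one_of(st.none(), st.integers(0, 40000)), min_size=7, max_size=7),
    low_goal=st.sampled_from([5000, 7000, 9000]),
    raise_by=st.sampled_from([1000, 3000]),
)
def test_raising_the_goal_never_promotes_status(steps, low_goal, raise_by):
    """Goal monotonicity: a higher goal can only demote adherent weeks."""
    rows = [
        _day("p1", 9, d, steps=v) for d, v in enumerate(steps, start=1) if v is not None
    ]
    grid = _grid_from_raw(rows, ["p1"], [9])
    _, prop_low = classify.weekly_step_proportion(grid, low_goal)
    _, prop_high = classify.weekly_step_proportion(grid, low_goal + raise_by)
    monitored = any(v is not None for v in steps)
    status_low = classify.classify_week(monitored, prop_low >= 100)
    status_high = classify.classify_week(monitored, prop_high >= 100)
    assert status_high <= status_low
    if status_high != status_low:
        assert status_low is Status.ADHERENT and status_high is Status.SUBOPTIMAL


def test_metrics_classified_independently():
    rows = [_day("p1", 3, 1, steps=2000, mvpa=None)]
    grid = _grid_from_raw(rows, ["p1"], [3])
    weekly = classify.weekly_status(grid)
    by_metric = weekly.set_index("metric")["status"].astype(str)
    assert by_metric["steps"] == "suboptimal"
    assert by_metric["mvpa"] == "nonadherent"


def test_zero_submitted_days_is_nonadherent_regardless_of_values(small_weekly):
    zero_days = small_weekly[small_weekly["monitored_days"] == 0]
    assert (zero_days["status"].astype(str) == "nonadherent").all()


def test_participant_with_no_records_is_always_nonadherent():
    grid = _grid_from_raw([], ["p1"], list(range(3, 25)))
    weekly = classify.weekly_status(grid)
    assert len(weekly) == 22 * 2
    assert (weekly["status"].astype(str) == "nonadherent").all()
    for metric in (Metric.STEPS, Metric.MVPA):
        seq = classify.build_state_sequences(weekly, metric)
        assert (seq.to_numpy() == int(Status.NONADHERENT)).all()


def test_monitored_days_denominator_switch():
    rows = [_day("p1", 3, d, steps=7000) for d in range(1, 5)]  # 4 of 7 days
    grid = _grid_from_raw(rows, ["p1"], [3])
    fixed = classify.weekly_status(grid, step_denominator="fixed7")
    monitored = classify.weekly_status(grid, step_denominator="monitored")
    f = fixed[fixed["metric"] == "steps"].iloc[0]
    m = monitored[monitored["metric"] == "steps"].iloc[0]
    assert f["weekly_value"] == pytest.approx(4000)
    assert str(f["status"]) == "suboptimal"
    assert m["weekly_value"] == pytest.approx(7000)
    assert str(m["status"]) == "adherent"
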