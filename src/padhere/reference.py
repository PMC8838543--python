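"""Published adherence estimates from a 6-month online behavioral weight-loss cohort.

These constants summarize the adherence dynamics reported for the control
arm (N=212) of a 24-week online group-based weight-loss program that
prescribed concurrent step-based and minute-based physical-activity goals
(7000 rising to 10,000 steps/day; 50 rising to 200 MVPA minutes/week). They
serve two roles in this package:

* default parameters for the synthetic cohort generator, so the whole
  pipeline runs on data whose latent dynamics mirror a real program;
* ground truth for parameter-recovery checks of the transition and
  regression estimators.

Transition rows are stored as the printed percentages and row-normalized
exactly by :func:`row_normalized`; printed rows sum to 99.9-100.1 because of
rounding. Matrices are indexed (nonadherent, suboptimal, adherent) on both
axes, rows = status at the earlier week, columns = status at the later week.
"""

from __future__ import annotations

import numpy as np

from .states import Metric, Phase

#: Size of the reference cohort (all randomized control-arm participants).
N_PARTICIPANTS = 212

#: Week-3 status counts (nonadherent, suboptimal, adherent) per metric.
WEEK3_STATUS_COUNTS: dict[Metric, tuple[int, int, int]] = {
    Metric.STEPS: (29, 110, 73),
    Metric.MVPA: (29, 34, 149),
}


def row_normalized(rows) -> np.ndarray:
    """Return a row-stochastic matrix from rows of printed percentages."""
    m = np.asarray(rows, dtype=float)
    return m / m.sum(axis=1, keepdims=True)


def initial_distribution(metric: Metric) -> np.ndarray:
    """Week-3 status distribution (N, S, A) for ``metric``."""
    counts = np.asarray(WEEK3_STATUS_COUNTS[Metric(metric)], dtype=float)
    return counts / counts.sum()


# Week-to-week transition percentages during the graded goal phase, keyed by
# the later week of the pair (week 4 means the weeks 3->4 transition).
# The week-4 MVPA suboptimal row is stored as (2.9, 50.0, 47.1); the three
# entries of that row must total 100 and the suboptimal->nonadherent cell is
# the balancing value.
GRADED_WEEKLY_TRANSITIONS: dict[Metric, dict[int, np.ndarray]] = {
    Metric.STEPS: {
        4: row_normalized([[69.0, 31.0, 0.0], [1.8, 94.5, 3.6], [0.0, 43.8, 56.2]]),
        5: row_normalized([[81.8, 18.2, 0.0], [7.6, 82.1, 10.3], [0.0, 37.8, 62.2]]),
        6: row_normalized([[93.1, 6.9, 0.0], [5.7, 86.4, 7.9], [2.3, 41.9, 55.8]]),
        7: row_normalized([[86.1, 13.9, 0.0], [9.2, 82.3, 8.5], [0.0, 45.7, 54.3]]),
        8: row_normalized([[81.8, 18.2, 0.0], [7.3, 85.4, 7.3], [0.0, 51.6, 48.4]]),
    },
    Metric.MVPA: {
        4: row_normalized([[72.4, 24.1, 3.4], [2.9, 50.0, 47.1], [0.7, 10.7, 88.6]]),
        5: row_normalized([[82.6, 17.4, 0.0], [22.5, 62.5, 15.0], [1.3, 28.2, 70.5]]),
        6: row_normalized([[93.3, 6.7, 0.0], [9.9, 69.0, 21.1], [1.8, 24.3, 73.9]]),
        7: row_normalized([[83.8, 13.5, 2.7], [14.1, 78.2, 7.7], [1.0, 36.1, 62.9]]),
        8: row_normalized([[81.4, 18.6, 0.0], [10.9, 71.3, 17.8], [1.5, 29.4, 69.1]]),
    },
}

# Endpoint-conditional transition percentages: status at the end week of each
# phase given status at its start week (graded: week 3 -> week 8; fixed:
# week 8 -> week 24; full period: week 3 -> week 24). These are direct
# cross-tabulations of the two endpoint weeks, not products of the weekly
# matrices above.
PHASE_ENDPOINT_TRANSITIONS: dict[Metric, dict[Phase, np.ndarray]] = {
    Metric.STEPS: {
        Phase.GRADED: row_normalized(
            [[89.7, 10.3, 0.0], [15.5, 80.9, 3.6], [4.1, 67.1, 28.8]]
        ),
        Phase.FIXED: row_normalized(
            [[97.8, 2.2, 0.0], [44.0, 52.5, 3.5], [16.0, 52.0, 32.0]]
        ),
        Phase.FULL: row_normalized(
            [[100.0, 0.0, 0.0], [53.6, 44.5, 1.8], [31.5, 53.4, 15.1]]
        ),
    },
    Metric.MVPA: {
        Phase.GRADED: row_normalized(
            [[89.7, 10.3, 0.0], [14.7, 70.6, 14.7], [10.7, 49.0, 40.3]]
        ),
        Phase.FIXED: row_normalized(
            [[97.9, 0.0, 2.1], [46.0, 48.0, 6.0], [27.7, 36.9, 35.4]]
        ),
        Phase.FULL: row_normalized(
            [[100.0, 0.0, 0.0], [64.7, 29.4, 5.9], [39.6, 41.6, 18.8]]
        ),
    },
}

# Per-week odds ratio of occupying a less-adherent status (vs adherent),
# from the population-averaged logistic trend model, by metric and phase.
WEEKLY_DECAY_OR: dict[Metric, dict[Phase, float]] = {
    Metric.STEPS: {Phase.GRADED: 1.24, Phase.FIXED: 1.07, Phase.FULL: 1.09},
    Metric.MVPA: {Phase.GRADED: 1.39, Phase.FIXED: 1.06, Phase.FULL: 1.11},
}
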