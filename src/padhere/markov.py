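"""Empirical transition tables and marginal series of adherence states.

The weekly status sequences form a longitudinal categorical panel. This
module estimates, with a fixed denominator of all participants:

* weekly marginal proportions — percent of the cohort in each status at
  each week;
* empirical transition tables between any two weeks — direct
  cross-tabulations of the paired states, row-normalized to percentages.

Phase-endpoint tables (e.g. status at week 8 given status at week 3) are
direct two-week cross-tabulations, never products of intermediate weekly
matrices: chaining the weekly matrices would impose a first-order Markov
assumption that the direct tabulation does not require.

The API follows the model/results idiom: build an
:class:`AdherenceTransitionModel` from status sequences, call ``fit()``, and
query the returned :class:`TransitionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .states import PHASE_WEEKS, STATUS_LABELS, Metric, Phase

N_STATES = len(STATUS_LABELS)


@dataclass(frozen=True)
class TransitionTable:
    """3x3 cross-tabulation of statuses at two weeks.

    ``counts[i, j]`` is the number of participants in status ``i`` at
    ``from_week`` and status ``j`` at ``to_week`` (order: nonadherent,
    suboptimal, adherent). ``probabilities`` holds row percentages; rows
    with zero count are all-NaN (undefined, never fabricated zeros).
    """

    metric: Metric
    from_week: int
    to_week: int
    counts: pd.DataFrame
    probabilities: pd.DataFrame
    n: int

    def __post_init__(self) -> None:
        row_totals = self.counts.to_numpy().sum(axis=1)
        if int(row_totals.sum()) != self.n:
            raise DataError("transition counts do not total n participants")
        probs = self.probabilities.to_numpy()
        for i, total in enumerate(row_totals):
            if total == 0:
                if not np.isnan(probs[i]).all():
                    raise DataError("zero-count row must have undefined probabilities")
            elif abs(np.nansum(probs[i]) - 100.0) > 1e-6:
                raise DataError("defined probability row must sum to 100")

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        """Report-style row percentages rounded to ``decimals`` places."""
        return self.probabilities.round(decimals)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: one row per (from_status, to_status) cell."""
        rows = []
        for i, from_label in enumerate(STATUS_LABELS):
            for j, to_label in enumerate(STATUS_LABELS):
                rows.append(
                    {
                        "metric": self.metric.value,
                        "from_week": self.from_week,
                        "to_week": self.to_week,
                        "from_status": from_label,
                        "to_status": to_label,
                        "count": int(self.counts.iat[i, j]),
                        "probability_pct": float(self.probabilities.iat[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Transition table ({self.metric.value}), week {self.from_week} "
            f"-> week {self.to_week}, n={self.n}",
            self.rounded().to_string(),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class MarginalSeries:
    """Percent of the full cohort in each status, by week (fixed denominator)."""

    metric: Metric
    proportions: pd.DataFrame  # index week, columns status labels, values %
    n: int

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise DataError("weekly marginal percentages must sum to 100")

    def to_frame(self) -> pd.DataFrame:
        out = self.proportions.reset_index().melt(
            id_vars="week", var_name="status", value_name="percent"
        )
        out.insert(0, "metric", self.metric.value)
        return out.sort_values(["week", "status"], ignore_index=True)


class AdherenceTransitionModel:
    """Empirical transition/marginal estimator for one metric's sequences.

    Parameters
    ----------
    sequences
        Participant x week matrix of status codes (0/1/2) as produced by
        :func:`padhere.classify.build_state_sequences`.
    metric
        Which goal type the sequences describe.
    """

    def __init__(self, sequences: pd.DataFrame, metric: Metric):
        self.metric = Metric(metric)
        seq = sequences.copy()
        seq.columns = [int(c) for c in seq.columns]
        arr = seq.to_numpy()
        if arr.size == 0:
            raise DataError("no participants in sequences")
        if not np.isin(arr, [0, 1, 2]).all():
            raise DataError("status codes must be 0, 1 or 2")
        self.sequences = seq
        self.weeks = tuple(sorted(seq.columns))

    @classmethod
    def from_weekly_status(cls, weekly: pd.DataFrame, metric: Metric):
        from .classify import build_state_sequences

        return cls(build_state_sequences(weekly, metric), metric)

    @property
    def n(self) -> int:
        return len(self.sequences)

    def fit(self) -> "TransitionResults":
        """Tabulate the marginal series; transition tables are lazy."""
        arr = self.sequences[list(self.weeks)].to_numpy()
        counts = np.stack(
            [(arr == s).sum(axis=0) for s in range(N_STATES)], axis=1
        )  # weeks x states
        marg = pd.DataFrame(
            100.0 * counts / self.n,
            index=pd.Index(self.weeks, name="week"),
            columns=list(STATUS_LABELS),
        )
        return TransitionResults(
            model=self, marginals=MarginalSeries(self.metric, marg, self.n)
        )


@dataclass
class TransitionResults:
    """Fitted marginal series plus on-demand transition tables."""

    model: AdherenceTransitionModel
    marginals: MarginalSeries
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def metric(self) -> Metric:
        return self.model.metric

    @property
    def n(self) -> int:
        return self.model.n

    def marginal_proportions(self) -> MarginalSeries:
        return self.marginals

    def transition_table(self, from_week: int, to_week: int) -> TransitionTable:
        """Direct cross-tabulation of statuses at two (not necessarily
        consecutive) weeks."""
        from_week, to_week = int(from_week), int(to_week)
        if from_week >= to_week:
            raise DataError(
                f"from_week must precede to_week; got {from_week} >= {to_week}"
            )
        for w in (from_week, to_week):
            if w not in self.model.weeks:
                raise DataError(f"week {w} not present in sequences")
        key = (from_week, to_week)
        if key in self._cache:
            return self._cache[key]

        a = self.model.sequences[from_week].to_numpy()
        b = self.model.sequences[to_week].to_numpy()
        counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
        np.add.at(counts, (a, b), 1)
        row_totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(row_totals > 0, 100.0 * counts / row_totals, np.nan)
        labels = list(STATUS_LABELS)
        table = TransitionTable(
            metric=self.metric,
            from_week=from_week,
            to_week=to_week,
            counts=pd.DataFrame(counts, index=labels, columns=labels),
            probabilities=pd.DataFrame(probs, index=labels, columns=labels),
            n=self.n,
        )
        self._cache[key] = table
        return table

    def consecutive_tables(self, weeks=None) -> list[TransitionTable]:
        """One table per consecutive week pair (w-1, w) over ``weeks``."""
        weeks = sorted(int(w) for w in (weeks if weeks is not None else self.model.weeks))
        return [
            self.transition_table(v, w) for v, w in zip(weeks[:-1], weeks[1:])
        ]

    def phase_endpoint_table(self, phase: Phase) -> TransitionTable:
        """Endpoint-conditional table for a phase.

        Graded: week 3 -> week 8; fixed: week 8 -> week 24 (status at the
        fixed-phase end given status at the graded-phase end); full: week 3
        -> week 24.
        """
        phase = Phase(phase)
        if phase is Phase.GRADED:
            lo, hi = PHASE_WEEKS[Phase.GRADED]
        elif phase is Phase.FIXED:
            lo, hi = PHASE_WEEKS[Phase.GRADED][1], PHASE_WEEKS[Phase.FIXED][1]
        else:
            lo, hi = PHASE_WEEKS[Phase.FULL]
        return self.transition_table(lo, hi)

    def summary(self) -> str:
        head = (
            f"Adherence transitions ({self.metric.value}): n={self.n}, "
            f"weeks {self.model.weeks[0]}-{self.model.weeks[-1]}"
        )
        return "\n".join([head, "", "Weekly marginal percentages:",
                          self.marginals.proportions.round(1).to_string()])
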