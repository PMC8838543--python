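"""Population-averaged models of weekly adherence decay.

The scientific question: how do the odds of occupying a *less adherent*
status (suboptimal or nonadherent, versus the adherent reference) change
per week of the program, within each goal phase and for each goal metric?

The primary model collapses the three statuses into the binary outcome
``less_adherent = status != adherent`` and fits a population-averaged
(GEE-style) logistic regression with week as a continuous covariate,
exchangeable within-participant working correlation, and cluster-robust
(sandwich) standard errors — so the working-correlation choice affects
efficiency only, never validity. The exponentiated week coefficient is the
per-week odds ratio of being less adherent.

A secondary mode fits the full 3-category multinomial logit with an
independence working assumption and participant-clustered robust variance,
reporting both less-adherent contrasts (suboptimal vs adherent and
nonadherent vs adherent) separately.

Because the same participants underlie both goal metrics, the steps-versus
-minutes comparison stacks the two datasets and tests the week x goal-type
interaction with participant-clustered robust variance, rather than
treating the two fits as independent samples (a naive two-sample z test is
provided for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import DataError, DegenerateFitError
from .states import PHASE_WEEKS, Metric, Phase, Status

REGRESSION_COLUMNS = [
    "participant_id",
    "metric",
    "phase",
    "week",
    "week_c",
    "status",
    "less_adherent",
]

_STATUS_CODE = {s.label: int(s) for s in Status}


def build_regression_dataset(
    sequences: pd.DataFrame, metric: Metric, phase: Phase
) -> pd.DataFrame:
    """Long-format analysis rows for one metric and phase.

    ``sequences`` is the participant x week status-code matrix. Rows are
    restricted to the phase's weeks (graded 3-8, fixed 9-24, full 3-24) and
    ``week_c`` is the week centered at the phase's first week, so the
    intercept is the log-odds at phase entry and the week coefficient is a
    per-week trend.
    """
    phase = Phase(phase)
    lo, hi = PHASE_WEEKS[phase]
    weeks = [w for w in sorted(int(c) for c in sequences.columns) if lo <= w <= hi]
    if not weeks:
        raise DataError(f"sequences contain no weeks in phase {phase.value} ({lo}-{hi})")
    sub = sequences[weeks]
    long = sub.stack().rename("code").reset_index()
    long.columns = ["participant_id", "week", "code"]
    long["metric"] = Metric(metric).value
    long["phase"] = phase.value
    long["week_c"] = long["week"].astype(int) - lo
    long["status"] = long["code"].map({int(s): s.label for s in Status})
    long["less_adherent"] = (long["code"] != int(Status.ADHERENT)).astype(int)
    return long[REGRESSION_COLUMNS].sort_values(
        ["participant_id", "week"], ignore_index=True
    )


def _validate_panel(data: pd.DataFrame) -> None:
    missing = [c for c in ("participant_id", "week_c", "less_adherent") if c not in data]
    if missing:
        raise DataError(f"regression dataset is missing columns {missing}")
    if data["participant_id"].nunique() < 2:
        raise DegenerateFitError(
            "at least 2 participants are required: cluster-robust variance "
            "has no between-cluster information with a single cluster"
        )
    if data["week_c"].nunique() < 2:
        raise DegenerateFitError("at least 2 distinct weeks are required")
    outcome = data["less_adherent"].astype(int)
    if outcome.nunique() < 2:
        raise DegenerateFitError(
            "complete separation: every observation has the same outcome "
            f"(all less_adherent={int(outcome.iloc[0])})"
        )


@dataclass(frozen=True)
class AdherenceDecayResults:
    """Fitted per-week adherence-decay odds ratio with robust inference."""

    metric: str
    phase: str
    odds_ratio_per_week: float
    ci95: tuple[float, float]
    robust_se_log_or: float
    p_value: float
    intercept_log_odds: float
    n_participants: int
    n_observations: int
    working_correlation: str
    statsmodels_results: object = None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0 < lo <= self.odds_ratio_per_week <= hi):
            raise DataError("odds ratio must lie inside its confidence interval")

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"Weekly adherence decay ({self.metric}, {self.phase} phase)\n"
            f"  outcome: less adherent (vs adherent), population-averaged logistic\n"
            f"  working correlation: {self.working_correlation}; "
            f"robust (sandwich) SE\n"
            f"  n={self.n_participants} participants, "
            f"{self.n_observations} participant-weeks\n"
            f"  OR per week: {self.odds_ratio_per_week:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f}), p={self.p_value:.3g}"
        )


class AdherenceDecayModel:
    """Population-averaged logistic trend model for the less-adherent outcome.

    Parameters
    ----------
    data
        Long-format rows from :func:`build_regression_dataset` (or any
        DataFrame with ``participant_id``, ``week_c`` and ``less_adherent``).
    """

    def __init__(self, data: pd.DataFrame):
        _validate_panel(data)
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_sequences(cls, sequences: pd.DataFrame, metric: Metric, phase: Phase):
        return cls(build_regression_dataset(sequences, metric, phase))

    # -- fitting ---------------------------------------------------------

    def fit(self, cov_struct: str = "exchangeable") -> AdherenceDecayResults:
        """Fit the binary GEE and return the per-week odds ratio.

        ``cov_struct`` may be ``"exchangeable"`` (default) or
        ``"independence"``; inference always uses the robust sandwich
        covariance.
        """
        data = self.data
        structs = {
            "exchangeable": sm.cov_struct.Exchangeable,
            "independence": sm.cov_struct.Independence,
        }
        try:
            struct = structs[cov_struct]()
        except KeyError:
            raise DataError(f"unknown working correlation {cov_struct!r}") from None

        endog = data["less_adherent"].astype(int).to_numpy()
        exog = sm.add_constant(data[["week_c"]].astype(float), has_constant="add")
        model = sm.GEE(
            endog,
            exog,
            groups=data["participant_id"].to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=struct,
        )
        res = model.fit(maxiter=200)
        beta = float(res.params["week_c"])
        se = float(res.bse["week_c"])
        ci = res.conf_int().loc["week_c"]
        if not np.all(np.isfinite([beta, se, ci[0], ci[1]])) or se <= 0:
            raise DegenerateFitError(
                "estimating equations diverged (non-finite estimate or "
                "robust SE); the outcome is likely quasi-separated in week"
            )
        return AdherenceDecayResults(
            metric=str(data["metric"].iloc[0]) if "metric" in data else "",
            phase=str(data["phase"].iloc[0]) if "phase" in data else "",
            odds_ratio_per_week=float(np.exp(beta)),
            ci95=(float(np.exp(ci[0])), float(np.exp(ci[1]))),
            robust_se_log_or=se,
            p_value=float(res.pvalues["week_c"]),
            intercept_log_odds=float(res.params["const"]),
            n_participants=int(data["participant_id"].nunique()),
            n_observations=int(len(data)),
            working_correlation=cov_struct,
            statsmodels_results=res,
        )

    def fit_multinomial(self) -> pd.DataFrame:
        """Secondary mode: 3-category multinomial logit, adherent reference.

        Fits an (independence working assumption) multinomial logit of
        status on week with participant-clustered robust variance and
        returns one row per less-adherent contrast with the per-week OR,
        robust SE, 95% CI and p-value.
        """
        data = self.data
        if "status" not in data:
            raise DataError("multinomial mode requires the 3-level status column")
        # Recode so ADHERENT is outcome 0 (the statsmodels reference category).
        recode = {
            Status.ADHERENT.label: 0,
            Status.SUBOPTIMAL.label: 1,
            Status.NONADHERENT.label: 2,
        }
        y = data["status"].astype(str).map(recode)
        if y.isna().any():
            raise DataError("unknown status labels in regression dataset")
        if y.nunique() < 2:
            raise DegenerateFitError("all observations share one status")
        exog = sm.add_constant(data[["week_c"]].astype(float), has_constant="add")
        model = sm.MNLogit(y.to_numpy(), exog)
        res = model.fit(
            disp=False,
            cov_type="cluster",
            cov_kwds={"groups": data["participant_id"].to_numpy()},
        )
        contrast_names = {0: Status.SUBOPTIMAL.label, 1: Status.NONADHERENT.label}
        present = sorted(set(y) - {0})
        rows = []
        params = np.asarray(res.params)  # shape (k_exog, n_categories-1)
        bse = np.asarray(res.bse)
        for col, cat in enumerate(present):
            beta = params[1, col]
            se = bse[1, col]
            z = beta / se
            rows.append(
                {
                    "contrast": f"{contrast_names[cat - 1]}_vs_adherent",
                    "odds_ratio_per_week": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                    "robust_se_log_or": float(se),
                    "p_value": float(2 * norm.sf(abs(z))),
                }
            )
        return pd.DataFrame(rows)

    # -- simulation ------------------------------------------------------

    @staticmethod
    def simulate_panel(
        n_participants: int,
        weeks,
        baseline_prob: float,
        weekly_or: float,
        *,
        rho: float = 0.5,
        rng: np.random.Generator | None = None,
        metric: str = "steps",
        phase: str = "graded",
    ) -> pd.DataFrame:
        """Simulate correlated binary less-adherent outcomes.

        The marginal model is ``logit P(Y_iw = 1) = logit(baseline_prob) +
        log(weekly_or) * (w - weeks[0])``; within-participant dependence is
        induced by a Gaussian copula with exchangeable correlation ``rho``
        (a shared participant-level normal plus i.i.d. noise), which leaves
        the marginal probabilities exact — precisely the estimand of the
        population-averaged fit.
        """
        if not 0 <= rho < 1:
            raise DataError(f"copula correlation must be in [0, 1), got {rho}")
        if not 0 < baseline_prob < 1:
            raise DataError("baseline_prob must be strictly inside (0, 1)")
        rng = rng if rng is not None else np.random.default_rng()
        weeks = np.asarray(sorted(int(w) for w in weeks))
        t = weeks - weeks[0]
        p = expit(logit(baseline_prob) + np.log(weekly_or) * t)
        thresholds = norm.ppf(p)
        shared = rng.standard_normal((n_participants, 1))
        noise = rng.standard_normal((n_participants, len(weeks)))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        y = (z < thresholds[None, :]).astype(int)

        ids = np.repeat([f"sim{i:06d}" for i in range(n_participants)], len(weeks))
        week_col = np.tile(weeks, n_participants)
        out = pd.DataFrame(
            {
                "participant_id": ids,
                "metric": metric,
                "phase": phase,
                "week": week_col,
                "week_c": week_col - weeks[0],
                "less_adherent": y.ravel(),
            }
        )
        out["status"] = np.where(
            out["less_adherent"] == 1,
            Status.SUBOPTIMAL.label,
            Status.ADHERENT.label,
        )
        return out[REGRESSION_COLUMNS]


@dataclass(frozen=True)
class GoalTypeComparison:
    """Steps-versus-minutes contrast of the weekly decay slope."""

    phase: str
    delta_log_or: float  # minutes slope minus steps slope
    robust_se: float
    wald_z: float
    p_value: float
    or_steps: float
    or_minutes: float
    n_participants: int

    def summary(self) -> str:
        return (
            f"Goal-type comparison ({self.phase} phase): per-week OR "
            f"{self.or_steps:.3f} (steps) vs {self.or_minutes:.3f} (minutes); "
            f"week x goal-type interaction delta log-OR = "
            f"{self.delta_log_or:.4f} (robust SE {self.robust_se:.4f}), "
            f"z = {self.wald_z:.3f}, p = {self.p_value:.3g}"
        )


def compare_goal_types(
    data_steps: pd.DataFrame, data_minutes: pd.DataFrame
) -> GoalTypeComparison:
    """Test whether adherence decays faster for one goal type.

    Stacks the two per-metric datasets (same participants, same phase),
    fits the population-averaged logistic model with week, goal-type and
    week x goal-type terms, and clusters the robust variance on the
    participant — each participant contributes rows to both goal types, so
    the two slopes are dependent and a stacked interaction test is the
    valid comparison. The reported p-value is the Wald test of the
    interaction.
    """
    for df in (data_steps, data_minutes):
        _validate_panel(df)
    p_steps = set(data_steps["participant_id"])
    p_minutes = set(data_minutes["participant_id"])
    if p_steps != p_minutes:
        raise DataError(
            "the two datasets must cover the same participants; "
            f"{len(p_steps ^ p_minutes)} ids differ"
        )
    if set(data_steps["week_c"]) != set(data_minutes["week_c"]):
        raise DataError("the two datasets must cover the same phase weeks")

    stacked = pd.concat(
        [data_steps.assign(is_minutes=0), data_minutes.assign(is_minutes=1)],
        ignore_index=True,
    )
    exog = pd.DataFrame(
        {
            "const": 1.0,
            "week_c": stacked["week_c"].astype(float),
            "is_minutes": stacked["is_minutes"].astype(float),
            "week_x_minutes": stacked["week_c"].astype(float)
            * stacked["is_minutes"].astype(float),
        }
    )
    model = sm.GEE(
        stacked["less_adherent"].astype(int).to_numpy(),
        exog,
        groups=stacked["participant_id"].to_numpy(),
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Independence(),
    )
    res = model.fit(maxiter=200)
    delta = float(res.params["week_x_minutes"])
    se = float(res.bse["week_x_minutes"])
    if se < 1e-9:
        # Identical stacked datasets: the interaction contrast is exactly 0
        # with exactly 0 sandwich variance; report the null rather than 0/0.
        if abs(delta) < 1e-9:
            delta, z = 0.0, 0.0
        else:
            raise DegenerateFitError(
                "zero robust variance for a non-zero interaction estimate"
            )
    else:
        z = delta / se
    beta_steps = float(res.params["week_c"])
    phase = str(data_steps["phase"].iloc[0]) if "phase" in data_steps else ""
    return GoalTypeComparison(
        phase=phase,
        delta_log_or=delta,
        robust_se=se,
        wald_z=z,
        p_value=float(2 * norm.sf(abs(z))),
        or_steps=float(np.exp(beta_steps)),
        or_minutes=float(np.exp(beta_steps + delta)),
        n_participants=int(stacked["participant_id"].nunique()),
    )


def paired_z_test(
    fit_a: AdherenceDecayResults, fit_b: AdherenceDecayResults
) -> tuple[float, float]:
    """Naive two-sample z on two log-ORs (sensitivity check only).

    Ignores the within-participant dependence between the two fits; prefer
    :func:`compare_goal_types` for the primary comparison.
    """
    delta = np.log(fit_b.odds_ratio_per_week) - np.log(fit_a.odds_ratio_per_week)
    se = float(np.hypot(fit_a.robust_se_log_or, fit_b.robust_se_log_or))
    z = float(delta / se)
    return z, float(2 * norm.sf(abs(z)))
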