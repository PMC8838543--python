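"""End-to-end pipeline: logs -> cleaning -> classification -> estimates.

``run_pipeline`` composes every stage and writes a reproducible report
bundle (CSV data products plus a JSON manifest with configuration, row
counts and content hashes). Identical configuration + seed yields
byte-identical bundles. On any stage failure the partially written outputs
are removed and the error is re-raised with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cleaning, simulate
from .errors import ConfigurationError, DataError, PadhereError
from .gee import AdherenceDecayModel, compare_goal_types
from .markov import AdherenceTransitionModel
from .schedule import GoalSchedule
from .states import METRICS, Metric, Phase

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to analyze and how.

    Exactly one of ``input_csv`` (real or pre-generated logs) and
    ``simulation`` (generate a synthetic cohort) must be set.
    """

    input_csv: str | None = None
    simulation: simulate.SimulationConfig | None = None
    #: optional roster of all participant ids (list, or path to a one-column
    #: CSV); participants with no submitted records cannot be recovered from
    #: the logs alone, yet they belong in every denominator
    roster: object = None
    schedule: GoalSchedule = field(default_factory=GoalSchedule.default)
    step_denominator: str = "fixed7"
    implausible_counts_as_monitoring: bool = True
    phases: tuple[Phase, ...] = (Phase.GRADED, Phase.FIXED, Phase.FULL)
    out_dir: str = "padhere_report"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of input_csv / simulation must be set"
            )
        self.phases = tuple(Phase(p) for p in self.phases)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        # -- input ------------------------------------------------------
        stage = "input"
        if config.simulation is not None:
            states, logs = simulate.simulate_cohort(config.simulation, config.schedule)
            roster = simulate.participant_ids(config.simulation)
            emit("daily_logs.csv", lambda p: simulate.write_logs(logs, p, config.simulation))
            weeks = config.simulation.weeks
        else:
            logs = cleaning.read_daily_logs(config.input_csv)
            roster = sorted(logs["participant_id"].astype(str).unique())
            weeks = tuple(sorted(set(int(w) for w in logs["week"]) & set(config.schedule.weeks)))
            if not weeks:
                weeks = config.schedule.weeks
        if config.roster is not None:
            if isinstance(config.roster, (str, Path)):
                listed = [
                    line.strip()
                    for line in Path(config.roster).read_text().splitlines()
                    if line.strip() and line.strip() != "participant_id"
                ]
            else:
                listed = [str(p) for p in config.roster]
            missing_ids = set(logs["participant_id"].astype(str)) - set(listed)
            if missing_ids:
                raise DataError(
                    f"logs mention participants absent from roster: {sorted(missing_ids)[:10]}"
                )
            roster = sorted(listed)
        if not roster:
            raise DataError("no participants")
        emit(
            "roster.csv",
            lambda p: p.write_text("participant_id\n" + "\n".join(roster) + "\n"),
        )

        # -- cleaning ---------------------------------------------------
        stage = "cleaning"
        clean = cleaning.clean_logs(logs)
        clean = clean[clean["week"].isin(weeks)]
        grid = cleaning.expand_to_full_grid(clean, roster, weeks)
        subs = cleaning.substitution_counts(grid)
        logger.info("substitution counts: %s", subs)
        emit("clean_logs.csv", lambda p: grid.to_csv(p, index=False))

        # -- classification --------------------------------------------
        stage = "classification"
        weekly = classify.weekly_status(
            grid,
            config.schedule,
            step_denominator=config.step_denominator,
            implausible_counts_as_monitoring=config.implausible_counts_as_monitoring,
        )
        emit("weekly_status.csv", lambda p: weekly.to_csv(p, index=False))

        # -- transitions -----------------------------------------------
        stage = "transitions"
        marginal_frames = []
        table_frames = []
        transition_report: dict = {}
        for metric in METRICS:
            results = AdherenceTransitionModel.from_weekly_status(weekly, metric).fit()
            marginal_frames.append(results.marginal_proportions().to_frame())
            report_m: dict = {"n": results.n, "phases": {}}
            for phase in config.phases:
                phase_weeks = [w for w in weeks if w in config.schedule.phase_weeks(phase)]
                if phase is not Phase.FULL and len(phase_weeks) >= 2:
                    for table in results.consecutive_tables(phase_weeks):
                        table_frames.append(table.to_frame().assign(kind="weekly"))
                try:
                    endpoint = results.phase_endpoint_table(phase)
                except (DataError, KeyError):
                    continue
                table_frames.append(endpoint.to_frame().assign(kind="endpoint"))
                probs = endpoint.probabilities.round(1)
                report_m["phases"][phase.value] = {
                    "endpoint_weeks": [endpoint.from_week, endpoint.to_week],
                    "probabilities_pct": json.loads(
                        probs.to_json(orient="index")
                    ),
                }
            transition_report[metric.value] = report_m
        emit(
            "marginal_series.csv",
            lambda p: pd.concat(marginal_frames, ignore_index=True).to_csv(p, index=False),
        )
        emit(
            "transition_tables.csv",
            lambda p: pd.concat(table_frames, ignore_index=True).to_csv(p, index=False),
        )
        emit(
            "transition_report.json",
            lambda p: p.write_text(json.dumps(transition_report, indent=2, sort_keys=True)),
        )

        # -- regression -------------------------------------------------
        stage = "regression"
        reg_rows = []
        cmp_rows = []
        sequences = {
            metric: classify.build_state_sequences(weekly, metric) for metric in METRICS
        }
        for phase in config.phases:
            datasets = {}
            for metric in METRICS:
                try:
                    model = AdherenceDecayModel.from_sequences(
                        sequences[metric], metric, phase
                    )
                    fit = model.fit()
                except PadhereError as exc:
                    logger.warning("decay fit skipped (%s, %s): %s", metric.value, phase.value, exc)
                    continue
                datasets[metric] = model.data
                reg_rows.append(
                    {
                        "metric": metric.value,
                        "phase": phase.value,
                        "odds_ratio": fit.odds_ratio_per_week,
                        "ci_low": fit.ci95[0],
                        "ci_high": fit.ci95[1],
                        "p_value": fit.p_value,
                        "n_participants": fit.n_participants,
                        "n_observations": fit.n_observations,
                    }
                )
            if len(datasets) == 2:
                comparison = compare_goal_types(
                    datasets[Metric.STEPS], datasets[Metric.MVPA]
                )
                cmp_rows.append(
                    {
                        "phase": phase.value,
                        "or_steps": comparison.or_steps,
                        "or_minutes": comparison.or_minutes,
                        "delta_log_or": comparison.delta_log_or,
                        "wald_z": comparison.wald_z,
                        "p_value": comparison.p_value,
                    }
                )
        emit(
            "weekly_decay.csv",
            lambda p: pd.DataFrame(reg_rows).to_csv(p, index=False),
        )
        emit(
            "goal_type_comparison.csv",
            lambda p: pd.DataFrame(cmp_rows).to_csv(p, index=False),
        )

        # -- manifest ---------------------------------------------------
        stage = "manifest"
        try:
            version = importlib_metadata.version("padhere")
        except importlib_metadata.PackageNotFoundError:
            version = "unknown"
        manifest = {
            "package": {"name": "padhere", "version": version},
            "library_versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "config": {
                "input_csv": config.input_csv,
                "simulation": (
                    config.simulation.provenance() if config.simulation else None
                ),
                "step_denominator": config.step_denominator,
                "implausible_counts_as_monitoring": config.implausible_counts_as_monitoring,
                "phases": [p.value for p in config.phases],
                "schedule": config.schedule.to_rows(),
            },
            "substitution_counts": subs,
            "row_counts": {
                "daily_logs": int(len(logs)),
                "clean_grid": int(len(grid)),
                "weekly_status": int(len(weekly)),
            },
            "n_participants": len(roster),
            "outputs": {p.name: _sha256(p) for p in written},
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PadhereError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise PadhereError(f"[stage: {stage}] {exc}") from exc
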