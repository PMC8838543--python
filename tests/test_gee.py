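import numpy as np
import pandas as pd
import pytest

from padhere.errors import DataError, DegenerateFitError
from padhere.gee import (
    AdherenceDecayModel,
    build_regression_dataset,
    compare_goal_types,
    paired_z_test,
)
from padhere.states import Metric, Phase, Status


def _sequences(n, weeks, rng=None, p_less=0.5):
    rng = rng or np.random.default_rng(0)
    codes = np.where(rng.random((n, len(weeks))) < p_less, 1, 2)
    seq = pd.DataFrame(codes, columns=list(weeks))
    seq.index = [f"p{i:05d}" for i in range(n)]
    return seq


class TestBuildDataset:
    def test_graded_row_count_and_centering(self):
        seq = _sequences(212, range(3, 25))
        data = build_regression_dataset(seq, Metric.STEPS, Phase.GRADED)
        assert len(data) == 212 * 6
        assert sorted(data["week"].unique()) == [3, 4, 5, 6, 7, 8]
        assert sorted(data["week_c"].unique()) == [0, 1, 2, 3, 4, 5]

    def test_full_phase_row_count(self):
        seq = _sequences(212, range(3, 25))
        data = build_regression_dataset(seq, Metric.MVPA, Phase.FULL)
        assert len(data) == 212 * 22

    def test_always_adherent_participant_never_less_adherent(self):
        seq = pd.DataFrame([[2] * 6], columns=range(3, 9), index=["p0"])
        seq = pd.concat([seq, _sequences(3, range(3, 9))])
        data = build_regression_dataset(seq, Metric.STEPS, Phase.GRADED)
        assert (data.loc[data["participant_id"] == "p0", "less_adherent"] == 0).all()

    def test_less_adherent_collapses_both_lower_states(self):
        seq = pd.DataFrame([[0, 1, 2]], columns=[3, 4, 5], index=["p0"])
        seq = pd.concat([seq, pd.DataFrame([[2, 0, 1]], columns=[3, 4, 5], index=["p1"])])
        data = build_regression_dataset(seq, Metric.STEPS, Phase.GRADED)
        by = data.set_index(["participant_id", "week"])["less_adherent"]
        assert by[("p0", 3)] == 1 and by[("p0", 4)] == 1 and by[("p0", 5)] == 0


class TestFitWeeklyDecay:
    def test_null_model_or_near_one(self):
        """Constant outcome probability across weeks: CI covers OR=1."""
        rng = np.random.default_rng(42)
        data = AdherenceDecayModel.simulate_panel(
            10_000, range(3, 9), 0.5, 1.0, rho=0.4, rng=rng
        )
        fit = AdherenceDecayModel(data).fit()
        # estimate within 3 robust SEs of the null and tightly around 1
        assert abs(np.log(fit.odds_ratio_per_week)) < 3 * fit.robust_se_log_or
        assert abs(fit.odds_ratio_per_week - 1.0) < 0.02

    @pytest.mark.parametrize("truth", [1.24, 1.39])
    def test_recovers_generating_slope(self, truth):
        rng = np.random.default_rng(7)
        data = AdherenceDecayModel.simulate_panel(
            4000, range(3, 9), 0.5, truth, rho=0.5, rng=rng
        )
        fit = AdherenceDecayModel(data).fit()
        assert abs(np.log(fit.odds_ratio_per_week) - np.log(truth)) < (
            3 * fit.robust_se_log_or
        )

    def test_ci_coverage_near_nominal(self):
        """95% Wald CI covers the generating OR in most of 60 replicates."""
        truth, hits = 1.3, 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            data = AdherenceDecayModel.simulate_panel(
                212, range(3, 9), 0.5, truth, rho=0.5, rng=rng
            )
            lo, hi = AdherenceDecayModel(data).fit().ci95
            hits += lo <= truth <= hi
        assert hits / reps >= 0.85

    def test_single_participant_rejected(self):
        data = pd.DataFrame(
            {
                "participant_id": ["p0"] * 6,
                "week_c": range(6),
                "less_adherent": [0, 1, 0, 1, 0, 1],
            }
        )
        with pytest.raises(DegenerateFitError, match="2 participants"):
            AdherenceDecayModel(data)

    def test_constant_outcome_rejected_as_separation(self):
        data = pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{i}" for i in range(5)], 3),
                "week_c": np.tile([0, 1, 2], 5),
                "less_adherent": 1,
            }
        )
        with pytest.raises(DegenerateFitError, match="separation"):
            AdherenceDecayModel(data)

    def test_estimates_invariant_to_relabeling_and_row_order(self):
        rng = np.random.default_rng(5)
        data = AdherenceDecayModel.simulate_panel(300, range(3, 9), 0.5, 1.2, rng=rng)
        fit = AdherenceDecayModel(data).fit()
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabel = {p: f"z{idx}" for idx, p in enumerate(sorted(set(data["participant_id"])))}
        shuffled["participant_id"] = shuffled["participant_id"].map(relabel)
        fit2 = AdherenceDecayModel(shuffled).fit()
        assert fit2.odds_ratio_per_week == pytest.approx(fit.odds_ratio_per_week, rel=1e-8)
        assert fit2.robust_se_log_or == pytest.approx(fit.robust_se_log_or, rel=1e-8)

    def test_collapsing_consistency_without_suboptimal_rows(self):
        """With no suboptimal observation, the binary fit equals a
        nonadherent-vs-adherent fit on the same rows."""
        rng = np.random.default_rng(8)
        data = AdherenceDecayModel.simulate_panel(500, range(3, 9), 0.4, 1.25, rng=rng)
        data["status"] = np.where(
            data["less_adherent"] == 1,
            Status.NONADHERENT.label,
            Status.ADHERENT.label,
        )
        fit = AdherenceDecayModel(data).fit()
        relabeled = data.copy()
        relabeled["less_adherent"] = (
            relabeled["status"] == Status.NONADHERENT.label
        ).astype(int)
        fit2 = AdherenceDecayModel(relabeled).fit()
        assert fit2.odds_ratio_per_week == pytest.approx(fit.odds_ratio_per_week)

    def test_multinomial_mode_reports_both_contrasts(self):
        rng = np.random.default_rng(3)
        n, weeks = 400, list(range(3, 9))
        codes = rng.choice([0, 1, 2], size=(n, len(weeks)), p=[0.2, 0.4, 0.4])
        seq = pd.DataFrame(codes, columns=weeks, index=[f"p{i}" for i in range(n)])
        model = AdherenceDecayModel.from_sequences(seq, Metric.STEPS, Phase.GRADED)
        table = model.fit_multinomial()
        assert set(table["contrast"]) == {
            "suboptimal_vs_adherent",
            "nonadherent_vs_adherent",
        }
        assert (table["odds_ratio_per_week"] > 0).all()
        assert ((table["ci_low"] <= table["odds_ratio_per_week"])
                & (table["odds_ratio_per_week"] <= table["ci_high"])).all()


class TestCompareGoalTypes:
    def test_identical_datasets_give_null_interaction(self):
        rng = np.random.default_rng(12)
        data = AdherenceDecayModel.simulate_panel(400, range(3, 9), 0.5, 1.3, rng=rng)
        other = data.copy()
        other["metric"] = "mvpa"
        cmp = compare_goal_types(data, other)
        assert cmp.delta_log_or == pytest.approx(0.0, abs=1e-10)
        assert cmp.p_value == pytest.approx(1.0, abs=1e-6)

    def test_interaction_sign_matches_true_slope_difference(self):
        hits = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(2000 + r)
            steps = AdherenceDecayModel.simulate_panel(
                1000, range(3, 9), 0.5, 1.15, rho=0.4, rng=rng
            )
            minutes = AdherenceDecayModel.simulate_panel(
                1000, range(3, 9), 0.5, 1.45, rho=0.4, rng=rng, metric="mvpa"
            )
            minutes["participant_id"] = steps["participant_id"].to_numpy()
            cmp = compare_goal_types(steps, minutes)
            hits += cmp.delta_log_or > 0
        assert hits / reps >= 0.95

    def test_type_i_error_controlled_under_equal_slopes(self):
        rejections = 0
        reps = 120
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            steps = AdherenceDecayModel.simulate_panel(
                300, range(3, 9), 0.5, 1.25, rho=0.4, rng=rng
            )
            minutes = AdherenceDecayModel.simulate_panel(
                300, range(3, 9), 0.5, 1.25, rho=0.4, rng=rng, metric="mvpa"
            )
            minutes["participant_id"] = steps["participant_id"].to_numpy()
            rejections += compare_goal_types(steps, minutes).p_value < 0.05
        assert rejections / reps <= 0.10

    def test_differing_participant_sets_rejected(self):
        rng = np.random.default_rng(4)
        a = AdherenceDecayModel.simulate_panel(50, range(3, 9), 0.5, 1.2, rng=rng)
        b = AdherenceDecayModel.simulate_panel(40, range(3, 9), 0.5, 1.2, rng=rng)
        with pytest.raises(DataError, match="same participants"):
            compare_goal_types(a, b)

    def test_paired_z_agrees_in_sign_with_stacked_test(self):
        rng = np.random.default_rng(21)
        steps = AdherenceDecayModel.simulate_panel(2000, range(3, 9), 0.5, 1.1, rng=rng)
        minutes = AdherenceDecayModel.simulate_panel(
            2000, range(3, 9), 0.5, 1.5, rng=rng, metric="mvpa"
        )
        minutes["participant_id"] = steps["participant_id"].to_numpy()
        fit_s = AdherenceDecayModel(steps).fit()
        fit_m = AdherenceDecayModel(minutes).fit()
        z, p = paired_z_test(fit_s, fit_m)
        cmp = compare_goal_types(steps, minutes)
        assert np.sign(z) == np.sign(cmp.wald_z) == 1
        assert p < 0.05 and cmp.p_value < 0.05
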