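# Methods

## Adherence states and their measurement

Each participant-week-metric is assigned exactly one of three ordered
states: nonadherent < suboptimally adherent < adherent. The state is a
deterministic function of two weekly indicators computed per metric:

* **self-monitoring** — true iff at least one record of that metric (any
  value, including 0) was submitted on one of the week's 7 days;
* **goal attainment** — true iff the attainment proportion is ≥ 100%,
  where for steps the proportion is `100 × (Σ cleaned daily steps / 7) /
  daily step goal` and for MVPA it is `100 × Σ cleaned daily minutes /
  weekly minute goal`.

Adherent = monitored ∧ met; suboptimal = monitored ∧ ¬met; nonadherent =
¬monitored. The pair (¬monitored, met) cannot arise from cleaned data
(with no submitted days every cleaned value is 0); if supplied directly to
`classify_week` it maps to nonadherent with a warning, encoding the
assumption that a participant who did not self-monitor also did not meet
the goal.

### Cleaning rules

A value of 0 is substituted for missing entries and for submitted but
implausible entries: daily steps outside [1000, 30000] and daily MVPA above
1080 minutes. The bounds themselves are plausible (exactly 1000, 30000 or
1080 passes through). The two rules are independent of the submission
indicator: an implausible submission still counts as self-monitoring. A
submitted step count of exactly 0 is a legitimate record; it falls under
the <1000 rule, so it contributes 0 to attainment while still counting as
monitoring — the IMPLAUSIBLE flag it receives is diagnostic only. Negative
values are rejected as malformed rather than cleaned. A configuration
switch (`implausible_counts_as_monitoring=False`) withdraws monitoring
credit from implausible-only days for sensitivity analysis.

### Step averaging denominator

The weekly step value divides the 7-day sum by a fixed 7, never by the
number of monitored days: zero-substitution happens before averaging, so
missing days drag the average down. This is the most literal reading of
the cleaning rule and is the default; `step_denominator="monitored"` is
available as a sensitivity alternative and materially changes
classifications when monitoring is sparse (a participant logging 7000
steps on 4 of 7 days is suboptimal under the default, adherent under the
alternative).

## Goal schedule

The built-in ladder prescribes goals for weeks 3–24 only: graded phase
weeks 3–8 (7000→10,000 steps/day in 1000-step increments every two weeks;
50→150 MVPA min/week in 50-minute increments), fixed phase weeks 9–24
(10,000 steps/day, 200 MVPA min/week). Weeks 1–2 are *absent* from the
schedule rather than carrying a 0 goal, so requesting a goal there raises
an error instead of silently classifying unprescribed weeks. Alternative
ladders load from YAML/JSON; construction validates full coverage of weeks
3–24, non-decreasing goals, and contiguous phases.

## Transition estimation

Transition tables are direct cross-tabulations of the paired states at two
weeks, row-normalized to percentages; rows with zero count are reported as
undefined (nulls), never as zeros. Phase-endpoint tables (week 3→8, week
8→24, week 3→24) are likewise direct tabulations: chaining the consecutive
weekly matrices would add a first-order Markov assumption the data need
not satisfy, and in general does not reproduce the direct table. All
participants contribute to every table — sequences are complete by
construction, with unobserved weeks classified nonadherent — so the
denominator is fixed at the cohort size, and marginal proportions use that
same denominator. Probabilities are stored at full precision and rounded
to 1 decimal only for report output.

## Adherence-decay regression

The three states are collapsed to the binary outcome `less adherent =
status ≠ adherent`, modeled with a population-averaged logistic regression
(GEE): week enters as a continuous covariate centered at the phase's first
week, the working correlation is exchangeable by default (independence
available), and inference always uses the cluster-robust sandwich
variance, so the working choice affects efficiency, not validity. The
per-week odds ratio is `exp(β_week)` with Wald 95% CI on the log scale.
Degenerate inputs fail loudly: a single participant (no between-cluster
information), fewer than two distinct weeks, an outcome with no variation
(separation), or diverged estimating equations each raise a specific
error.

A single collapsed OR is only one reading of "odds of a less adherent
status" for a 3-level outcome; the package therefore also provides a
secondary multinomial mode (`fit_multinomial`): a 3-category logit with
adherent as reference, independence working assumption, and
participant-clustered robust variance, reporting the suboptimal-vs-adherent
and nonadherent-vs-adherent per-week ORs separately. The binary collapse is
the primary mode because it yields the single per-phase OR the downstream
comparison needs.

**Steps versus minutes.** The same participants underlie both goal types,
so the two phase-specific slopes are dependent. The primary comparison
stacks both datasets, fits week + goal-type + week×goal-type with
independence working correlation and robust variance clustered on the
participant (whose rows span both goal types), and reports the Wald test
of the interaction. A naive two-sample z on the two log-ORs is provided
(`paired_z_test`) for sensitivity only. When the two stacked datasets are
numerically identical the interaction has exactly zero estimate and zero
sandwich variance; this 0/0 is reported as the null (z = 0, p = 1).

## Synthetic cohort generator

The generator emulates a 212-participant, 22-week (weeks 3–24) online
program cohort. Latent weekly states per metric follow a first-order
Markov chain: week-3 distributions (nonadherent, suboptimal, adherent) =
(29, 110, 73)/212 for steps and (29, 34, 149)/212 for MVPA; graded-phase
weekly transition matrices are the published estimates for that cohort
(row-normalized, since printed rows sum to 99.9–100.1). The source reports
no weekly matrices for the fixed phase, so the fixed-phase default is a
slowly-decaying matrix chosen once as realistic for a program's
maintenance period — nonadherence nearly absorbing (0.98), suboptimal
mostly persistent (0.90) with a small upward flow (0.04), adherent decaying
mainly into suboptimal (0.14):

```
            N      S      A
      N  0.98   0.02   0.00
      S  0.06   0.90   0.04
      A  0.02   0.14   0.84
```

Emission per monitored week: the number of monitored days is uniform on
1–7 (no distribution is reported); the weekly aggregate is drawn uniformly
as a fraction of the goal — (0.15, 0.9) of goal for suboptimal weeks,
(1.0, 1.3) for adherent weeks — and split across monitored days by a
symmetric-Dirichlet multinomial, with step day-values constrained to the
plausibility band [1000, 30000] (leftover monitored days become submitted
zero-reports). If an adherent step target exceeds the band capacity of the
drawn days (e.g. ≥ 70,000 steps on 2 days), the day set grows to the
minimum feasible size and a summary warning is logged; suboptimal targets
are instead capped at day capacity. Nonadherent weeks emit no records for
that metric. Contaminated days (probability `contamination_rate`) carry
values outside the plausibility bounds but still count as submitted.

Two consequences matter for interpretation. With `contamination_rate=0`
the emission is classification-faithful — running the pipeline on emitted
logs recovers the latent states exactly — which turns the generator into a
parameter-recovery oracle for the estimators. And the generator is *not*
physiologically realistic: no weekday/weekend structure, no
autocorrelation of daily values within a week, no coupling between weight
change and activity. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed state dynamics, not
fidelity of any real cohort's daily-value distributions. The two metrics'
latent chains are independent by default (`couple_monitoring=True` shares
monitored-day sets as a crude coupling); the joint distribution of the two
metrics' statuses is a modeling convenience, not an estimate.

`dropout_hazard` (default 0) adds permanent absorption into nonadherence
on top of the matrices. The default is 0 because the published *weekly*
matrices already carry positive nonadherent→suboptimal mass — weekly
nonadherence is not absorbing even though the full-period
endpoint-conditional persistence is 100%.

## Decay-model simulation oracle

`AdherenceDecayModel.simulate_panel` draws correlated binary panels from
the exact marginal model the GEE estimates: `logit P(Y_iw=1) = logit(p₀) +
log(OR)·(w − w₀)`, with within-participant dependence induced by a
Gaussian copula (shared participant-level normal plus i.i.d. noise,
exchangeable correlation ρ, default 0.5 — a moderate within-person
correlation typical of weekly behavioral outcomes). The copula leaves
marginal probabilities exact, so the population-averaged fit is consistent
for the generating OR; recovery tests use baseline p₀ equal to the week-3
less-adherent proportion of the reference cohort (139/212 steps, 63/212
MVPA).

## Problem sizes and numerical choices

Transition-cell recovery uses 100,000 two-week trajectories (binomial SE
≈ 0.1–0.2 percentage points per cell); OR recovery uses 10,000-participant
× 6-week panels (robust SE ≈ 0.005 on the log-OR); CI-coverage checks use
100 replicates at the reference cohort size of 212. Row-stochasticity is
enforced at tolerance 1e-9 on configs and 1e-6 percentage points on
estimates; GEE fits cap at 200 iterations and reject non-finite estimates.
Ties at goal boundaries resolve in favor of attainment (proportion exactly
100% is met), applied before any rounding.

## Known limitations

* The regression treats week as linear on the log-odds scale within a
  phase; real adherence decay may be nonlinear (the generator's Markov
  dynamics indeed induce mild nonlinearity, which is why transition-based
  and regression-based summaries are complementary, not redundant).
* Endpoint-conditional and weekly tables are purely descriptive; no
  smoothing, no hidden-Markov measurement model.
* The fixed-phase default matrix is a package choice, not an estimate;
  analyses of the fixed phase on default synthetic data characterize the
  pipeline, not any real cohort.
* Sequences are complete by construction (missing ⇒ nonadherent), so the
  models make no missing-at-random adjustments; if nonadherent weeks could
  hide goal-meeting activity, every estimate of nonadherence is an upper
  bound.
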