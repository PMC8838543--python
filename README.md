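# padhere

Weekly physical-activity adherence states, transition probabilities, and
adherence-decay models for behavioral weight-loss programs.

## The problem

Online behavioral weight-loss programs prescribe two kinds of weekly
physical-activity (PA) goals — a daily step target (e.g. 7000 rising to
10,000 steps/day) and a weekly target for minutes of moderate-to-vigorous
physical activity (MVPA, e.g. 50 rising to 200 min/week) — and ask
participants to self-report both metrics every day. Whether people keep up
with these goals, and *when* they stop, matters for tailoring treatment.
`padhere` implements the full analysis chain for this question, for
biostatisticians and intervention researchers working with daily
self-monitoring logs:

1. **Cleaning** — missing entries and implausible entries (daily steps
   below 1000 or above 30,000; more than 1080 MVPA minutes/day) are scored
   as 0 for goal computation, while the submission indicator — the basis of
   self-monitoring adherence — is never altered.
2. **Classification** — each participant-week-metric becomes one of three
   mutually exclusive states: **adherent** (self-monitored ≥1 day and met
   the goal), **suboptimally adherent** (self-monitored but missed the
   goal), **nonadherent** (no record that week). Step attainment is the
   7-day average divided by the daily goal; MVPA attainment is the weekly
   total divided by the weekly goal; ≥100% means met.
3. **Transition analysis** — weekly marginal proportions over a fixed
   denominator (all randomized participants), empirical 3×3 transition
   tables between any two weeks (row-normalized direct cross-tabulations;
   endpoint tables are *not* products of weekly matrices), per program
   phase (graded weeks 3–8, fixed weeks 9–24, full period).
4. **Adherence-decay regression** — a population-averaged (GEE) logistic
   model of the odds of occupying a *less adherent* state (vs adherent)
   with week as a continuous covariate, exchangeable working correlation
   and cluster-robust variance: `logit P(less adherent) = β₀ + β₁·week`,
   with `exp(β₁)` the per-week odds ratio. Steps-vs-minutes differences are
   tested by a stacked week×goal-type interaction clustered on participant.
5. **Synthetic cohort generator** — daily logs for a cohort whose latent
   weekly states follow configurable first-order Markov dynamics; defaults
   mirror a published 212-participant program cohort, so the whole pipeline
   runs with no external data and every estimator can be checked by
   parameter recovery.

## Worked example

```python
import padhere as pa

# simulate a cohort of 212 participants, weeks 3-24
cfg = pa.SimulationConfig(n_participants=212, seed=7)
states, logs = pa.simulate_cohort(cfg)

# clean -> classify -> weekly statuses
from padhere import cleaning, classify, simulate
grid = cleaning.expand_to_full_grid(cleaning.clean_logs(logs),
                                    simulate.participant_ids(cfg))
weekly = classify.weekly_status(grid)

# empirical transitions for step goals
res = pa.AdherenceTransitionModel.from_weekly_status(weekly, pa.Metric.STEPS).fit()
print(res.transition_table(3, 4).rounded())

# per-week decay of adherence during the graded phase
seq = pa.build_state_sequences(weekly, pa.Metric.STEPS)
fit = pa.AdherenceDecayModel.from_sequences(seq, pa.Metric.STEPS, pa.Phase.GRADED).fit()
print(fit.summary())
```

Output:

```
             nonadherent  suboptimal  adherent
nonadherent         71.4        28.6       0.0
suboptimal           0.0        95.6       4.4
adherent             0.0        26.8      73.2
Weekly adherence decay (steps, graded phase)
  outcome: less adherent (vs adherent), population-averaged logistic
  working correlation: exchangeable; robust (sandwich) SE
  n=212 participants, 1272 participant-weeks
  OR per week: 1.212 (95% CI 1.105-1.329), p=4.59e-05
```

The transition table says: of participants suboptimally adherent to the
step goal at week 3, 95.6% were still suboptimal at week 4 and 4.4% became
adherent. The regression says the odds of being less adherent grew about
21% per week during the ramp-up phase in this simulated cohort.

The same analyses are available from the shell:

```bash
padhere simulate --seed 7 --n 212 --out logs.csv
padhere run-all --logs logs.csv --out report/      # or --sim-config cfg.yaml
```

`run-all` writes cleaned logs, weekly statuses, marginal series, transition
tables, the decay-regression table and a manifest with content hashes;
identical config + seed reproduces the bundle byte for byte.

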