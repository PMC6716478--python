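# adhema

**Inhaler-adherence and ecological-momentary-assessment (EMA) analytics for
smartphone asthma-monitoring cohorts.**

Youth with high-risk asthma are often monitored at home with Bluetooth
inhaler caps that timestamp every actuation, an app for manual medication
entry, and a short daily EMA questionnaire (eight 4-point Likert items:
cough, wheeze, chest tightness, stressed, angry, bored, happy, relaxed).
Turning those raw streams into defensible adherence and symptom analytics
requires a chain of small, easy-to-get-wrong decisions — duplicate
device/manual records, medication "dumping", irregular self-report days —
and `adhema` implements that chain as a tested, reusable pipeline:

1. **Deduplication.** A manual entry duplicating a device-recorded actuation
   (same medication, within ±60 min by default) is removed, by one-to-one
   optimal matching; device records always win.
2. **Capped window adherence.** Controller adherence is computed per
   12-hour wall-clock window (AM [00:00, 12:00), PM [12:00, 24:00)) as
   min(taken, prescribed)/prescribed, so dumping many puffs at once never
   inflates adherence. Daily adherence averages the prescribed windows;
   cohort adherence is the unweighted mean over participant-days.
3. **Symptom days and new episodes.** A day with any symptom item ≥
   "A little" is an asthma symptom day. A *new symptom episode* starts at a
   symptom report on study day d ≥ 7 with at least one symptom-free report
   since the previous symptom report; enrollment-contiguous symptoms form
   the initial exacerbation, not an episode.
4. **Acquisition metrics** (fraction of days with any data / with EMA,
   pre/post app-redesign comparisons, reporting-frequency tests by age,
   gender, weekend/weekday).
5. **Association models.** Per item, a linear mixed model on the 0–100
   adherence scale:

   adherence<sub>id</sub> = β₀ + β_t·d + Σ<sub>ℓ</sub> β<sub>ℓ</sub>·1[item<sub>id</sub> = ℓ] + b_i + ε<sub>id</sub>,  b_i ~ N(0, σ²_b)

   with a participant random intercept, a linear study-day trend, REML
   estimation and Wald 95% CIs. β<sub>ℓ</sub> is the percentage-point change
   in daily adherence at Likert level ℓ versus the item's reference level.
   A sensitivity re-fit imputes non-report days at the reference level and
   flags estimates that move by more than their report-only standard error
   (the signature of informative missingness).
6. **Synthetic cohorts.** Because participant-level study data of this kind
   are rarely shareable, a calibrated generator produces cohorts with the
   same statistical structure (logit-normal adherence heterogeneity,
   episodic symptom runs, duplicate device/manual pairs, optionally
   adherence-linked reporting), with every latent quantity recorded for
   recovery testing.

## Worked example

```bash
adhema simulate --seed 7 --out sim
# wrote 541 events, 170 reports for 14 participants to sim
adhema run --events sim/events.csv --ema sim/ema.csv \
           --regimen sim/regimen.csv --out results
cat results/report.md
```

The report starts:

```
# Cohort monitoring report

- Group controller adherence: 27.4%
- Days with any data: 473/840 (56%)
- Days with EMA: 170/840 (20%)
- New asthma symptom episodes: 3
- Adherence, non-symptom-report vs non-report days: 25.0% vs 28.1% (P=0.289)
```

Reading it: this synthetic cohort of 14 youth followed for 60 days took
27.4% of prescribed controller doses (the generator's configured mean is
30%; a single cohort draw scatters around it), reported the EMA on 20% of
the 840 participant-days, and three new symptom episodes were detectable
from the reported days. The estimate table that follows is shaped like a
per-question summary — one row per EMA item, one column per Likert level,
`Reference` for the anchor level, `N/A` for levels never reported. This run prints, e.g.

```
| Are you bored? | Reference | +20.2% (9.6% to 30.8%) | +4.2% (-9.0% to 17.4%) | -4.2% (-20.8% to 12.5%) |
```

which reads "on days the participant reported being a little bored,
adherence ran 20.2 percentage points higher (95% CI 9.6–30.8) than on
non-bored days." (This default cohort plants *no* true item effects, so
that interval excluding zero is exactly the kind of chance finding a
14-participant pilot can produce — the coverage and recovery tests in
`tests/test_acceptance.py` quantify how often.)
`results/result.json` holds the same content machine-readably, and
`results/daily.csv` the participant-day table.

The library mirrors the CLI one-to-one:

```python
from adhema import SimulationConfig, generate_cohort, run_pipeline

cohort = generate_cohort(SimulationConfig(seed=7))
result = run_pipeline(cohort.events, cohort.reports, cohort.regimens)
print(result.group_adherence, result.episode_total)
```

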