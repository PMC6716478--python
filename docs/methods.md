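# Methods

This note documents the analysis pipeline's models, rules and numerical
choices, the design of the synthetic cohort generator, and what the test
suite's passing properties do and do not establish about real monitoring
data.

## Data model

Three input streams per participant, all in local civil time (dosing
windows are defined by wall clock, so the package performs no timezone
arithmetic):

* **Actuation events** — timestamped inhaler uses, `controller` or
  `rescue`, arriving via the Bluetooth cap (`device`) or manual app entry
  (`manual`).
* **EMA reports** — eight Likert items coded 0–3 (*Not at all / A little /
  A lot / Extremely*); individual items may be skipped within a report.
* **Regimen** — enrollment and end dates plus prescribed controller doses
  in the AM and PM windows. Study day 0 is the enrollment date; both the
  enrollment day and the final day are included in all denominators
  (configurable only by truncating the regimen dates).

## Deduplication

Patients manually log doses when the Bluetooth cap is out of range; when
the cap later syncs, the same physical actuation can appear twice. A manual
entry is treated as a duplicate when it can be paired with a device event
of the same participant and medication within ±`dedup_tolerance_minutes`
(default 60 — generous relative to observed sync jitter of minutes, tight
relative to the ≥ 12 h spacing of scheduled doses). Pairing is one-to-one:
the assignment maximizes the number of within-tolerance pairs and, among
such assignments, minimizes the total time discrepancy (solved exactly with
a linear-sum assignment). Device events are never removed, and every
removal is written to an audit log with its matched device event.

One caveat follows from the one-to-one rule: if two manual entries crowd a
single device event, only the nearest is removed, and a *second*
application of the deduplicator would then pair the device event with the
surviving manual entry. No one-to-one cancellation rule can be a fixed
point on such inputs, so deduplication is applied exactly once, at
ingestion. On event streams with the structure this data actually has — at
most one double-logged entry per device record, doses separated by well
over the tolerance — the operation is idempotent, and the test suite
verifies that on exactly that family of inputs.

## Adherence

* **Window adherence** = min(taken, prescribed) / prescribed per 12-hour
  window, AM [00:00, 12:00), PM [12:00, 24:00), half-open so a 12:00
  actuation is PM. The cap is the guard against overdosing and dumping
  (e.g. firing a burst of actuations before a clinic visit); the device
  buffer holds up to 400 events and the cap holds under exactly that
  injection.
* **Daily adherence** = mean of the *defined* window adherences (windows
  with prescribed > 0); undefined if nothing is prescribed that day.
  Averaging windows rather than pooling doses preserves the per-window
  guard: an AM double-dose cannot mask a PM miss.
* **Group adherence** = unweighted mean over all defined participant-days.
* Rescue actuations are ingested, deduplicated and count toward "any data"
  days, but never toward adherence, which is controller-only.

## Symptom days and new symptom episodes

Same-day reports are merged by per-item maximum. A merged day is an
**asthma symptom day** if cough, wheeze or chest tightness reaches the
symptom threshold (default level 1, *A little* — in this population wheeze
and chest tightness rarely exceed that level, so a higher threshold would
discard nearly all signal). Days without a report stay *undetermined*; they
are never coerced to symptom-free outside the explicit imputation analysis.

A **new symptom episode** starts at a symptomatic report on study day
d ≥ 7 (configurable) when at least one symptom-free report lies strictly
between the most recent prior symptomatic report — or enrollment, if none —
and d. Consequences of the definition, all covered by an exhaustive
equivalence test against a brute-force enumeration (every
symptomatic/clear/no-report sequence up to length 12):

* symptoms contiguous with enrollment (first report symptomatic, starting
  before day 7) form the *initial exacerbation* and never count as an
  episode; the initial run ends at the first symptom-free report however
  long it lasts, and a later symptom report can then start an episode;
* a first-ever report that is already symptomatic on or after day 7 is
  flagged `indeterminate_onset` and starts no episode — with no interim
  clear report there is no evidence the presenting episode had resolved;
* consecutive symptomatic reports without an intervening clear report
  belong to one episode, so detected episode starts are separated by clear
  reports and the detected count can never exceed the number of true
  symptomatic runs.

## Acquisition metrics and reporting-frequency tests

Cohort fractions of participant-days with any data (actuation or EMA) and
with EMA; optional pre/post-redesign comparison by Welch t-test on
per-participant percent-of-days values. Reporting frequency is compared by
Pearson correlation against age, Welch t-test between genders, and a
*paired* t-test on each participant's (weekend, weekday) report-fraction
pair, since the pairing is within participant. Degenerate inputs (a group
with fewer than two participants, zero variance) yield a flagged undefined
result rather than a spurious statistic.

## Association models

One linear mixed model per EMA item, plus a binary any-symptom model
(indicator: any symptom item at or above threshold):

```
adherence_pct[i,d] = β0 + βt·d + Σℓ βℓ·1[level[i,d] = ℓ] + b_i + ε[i,d]
```

* Outcome on the 0–100 scale, so fixed effects read directly as
  percentage-point changes in daily adherence.
* Observed non-reference Likert levels enter as categorical indicators.
  Reference levels: *Not at all* for cough, wheeze, chest-tight, stressed,
  angry, bored; *Extremely* for the positively worded happy and relaxed —
  every contrast is a departure from the untroubled state. Levels never
  observed are reported as `N/A`, never silently dropped.
* `study_day` enters as a linear fixed effect (repeated-measures trend);
  no higher-order terms at these sample sizes.
* Participant random intercept; REML estimation via statsmodels `MixedLM`;
  Wald 95% intervals and normal-theory p-values. With ~30 participants the
  z-versus-t distinction is below the Monte-Carlo resolution of the
  coverage tests (empirical coverage ≈ 95.5% at 30 participants × 60 days).
* Models are univariate per item (matching the one-row-per-question
  reporting layout), not mutually adjusted.
* Failure modes raise a diagnostic error naming the item: a single
  participant (random intercept unidentifiable), zero outcome variance, or
  a numerically failed fit. The pipeline degrades gracefully, reporting
  all other sections.

**Primary frame vs imputed frame.** The primary analysis keeps only days
with both an EMA report and defined adherence — non-report days are
excluded because they can carry systematically different adherence, and
folding them into the reference level would overstate symptom effects. The
sensitivity analysis re-fits with non-report (defined-adherence) days
included at each item's reference level, so imputed days inform only the
baseline. `sensitivity_compare` flags an estimate whose imputed counterpart
flips sign or moves by more than the report-only standard error. Under
reporting that is independent of adherence, imputation should narrow the
interval and leave the effect similar; a raised flag is evidence of
informative missingness. The model-free companion check compares mean
adherence on non-symptom-report days vs non-report days by Welch t-test.

## Synthetic cohort generator

Defaults encode the study conditions: 14 participants, 60 days, one
controller dose per 12-hour window, population-mean per-dose take
probability 0.30, EMA on 20% of days.

* **Adherence.** Each prescribed dose is Bernoulli(p_id) with
  logit(p) = μ + b_i (+ optional day-level jitter + item-exposure shifts on
  the probability scale). b_i ~ N(0, 1.0²) on the logit scale gives
  realistic heterogeneity (participant means roughly 0.08–0.65). μ is
  calibrated by Gauss–Hermite quadrature so the *population mean* take
  probability equals the configured 0.30 exactly, despite the logit-normal
  nonlinearity; boundary probabilities 0 and 1 are honored exactly.
* **Symptoms.** An optional enrollment-contiguous initial exacerbation
  (probability 0.5, geometric mean 3 days), then new runs at hazard
  0.02/day with geometric mean 3 days. On symptomatic days item levels are
  drawn mostly at *A little* (wheeze and chest tightness never beyond it by
  default), with at least one symptom item forced ≥ 1; mood items are drawn
  i.i.d. daily from configurable marginals (boredom present on ~half of
  days, stress and anger ~10%).
* **Events.** Dose timestamps are uniform within morning (06–11 h) and
  evening (18–23 h) sub-windows. A dose is recorded manually-only with
  probability 0.05 (cap failure); a device record spawns a jittered manual
  duplicate with probability 0.10 (jitter SD 5 min). Rescue use occurs on
  30% of symptomatic days and 2% of other days.
* **Reporting.** Daily report probability 0.20, plus
  `missingness_coef × (p_id − 0.30)`: a positive coefficient makes
  low-adherence days less likely to be reported (informative missingness);
  at the participant level this acts through b_i, and with `day_logit_sd`
  > 0 also within participant. Individual items are skipped with
  probability 0.02.
* **Truth block.** Random effects, daily take and report probabilities,
  the symptom calendar, run starts, the episode starts detectable under
  full observation, and those detectable under the realized reporting
  pattern — so every stage can be tested for recovery of known truth.
* **Determinism.** All draws run through per-participant `SeedSequence`
  substreams in fixed order; a seed reproduces the output byte-for-byte,
  and the episode-truth generator reuses the calendar substream so its
  calendars match the full cohort's.

For validating the mixed model itself the package uses a second, direct
generator (`generate_linear_frame`) that simulates straight from the model
equation (default: 30 participants × 60 days, random-intercept SD 10,
residual SD 25, planted +20 pp effect on ~15% of days). Parameter recovery
and interval coverage are measured there because the estimand is exact by
construction; the Bernoulli cohort generator then exercises the same
machinery end-to-end.

**What the generator does not emulate.** Binomial day-to-day outcome noise
rather than real behavioral autocorrelation; no weekday/weekend or seasonal
reporting structure (subgroup tests are validated on directly constructed
per-participant fractions instead); independence of symptoms and adherence
unless an item effect is planted; no device sync-delay artifacts beyond
timestamp jitter; and no mechanism producing the very high
any-data-day fractions a real cohort can show when partial dosing spreads
across most days — under the default Bernoulli model ~50–60% of days carry
data. Passing tests therefore establish correctness of the *rules and
estimators* under the stated generative assumptions, not fidelity of any
particular real cohort.

## Validation problem sizes

Exhaustive episode equivalence over all 3¹² twelve-day sequences; 1,000
random event sets against a naive adherence recount; 600 random ≤ 8-event
instances against exhaustive optimal-matching deduplication plus 300
realistic-structure idempotence instances; 500 replicates for planted-
effect recovery and coverage and 1,500 for null coverage (a coverage
proportion needs a tighter Monte-Carlo SE than a mean-bias check); 200
cohort replicates each for simulator calibration, MCAR null behavior and
informative-missingness sign recovery.

## Known limitations

* The Gaussian identity-link mixed model treats a 0–100 bounded, often
  highly discrete outcome (with one dose per window, daily adherence takes
  values 0/50/100) as continuous; estimates remain unbiased for the mean
  structure but residuals are heteroscedastic and intervals rely on
  large-ish cohort asymptotics.
* Wald intervals carry no small-sample (e.g. Kenward–Roger) correction; at
  14 participants they should be read as exploratory.
* The episode detector sees only reported days; sparse reporting both
  misses true episodes and, when a run straddles the day-7 boundary, can
  occasionally date an episode inside what full observation would have
  called the initial exacerbation.
* Deduplication is applied once at ingestion (see above); it is not a
  fixed-point operator on adversarial inputs.
* No dose-timing quality metrics, no lagged/causal analyses, no joint
  multi-item model.
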