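# Model and methods

`depsim` is a discrete-time (monthly) Markov microsimulation of the lifetime
course of depression in a closed birth cohort, built to quantify how much of
the population-level disease burden the healthcare system — prevention,
psychotherapy, and aftercare — removes, and how that changes when the reach
or effectiveness of each service is varied.

## States and clocks

Each simulated individual is, in any month, either *healthy* or *diseased*
(episode severity, comorbidity and pharmacotherapy are out of scope).  On
top of the dichotomous health state the model tracks history and service
clocks that the monthly transition probabilities depend on:

- number of episodes so far, months in the current episode, months in the
  current remission;
- care-pathway position: none → (help-seeking) → waiting → in treatment →
  (on remission) aftercare;
- a lifetime prevention-participation flag drawn at cohort entry.

## Monthly transition probabilities

All inputs are per-period probabilities; period conversion always uses the
complement-power formula `p_t = 1 − (1 − p_s)^(t/s)` (never the rate
approximation).  The worked anchors: a 53% yearly spontaneous remission
probability converts to 6.098% per month, and 12 treated months at the
default effectiveness give a 71.3% cumulative remission probability.

| transition | form | default |
|---|---|---|
| first onset | `conv(incidence(age) · scale, 12→1) · (1 − prevention_effect · participant)` | 1.14%/yr nominal level, age profile below |
| remission | flat 6.098%/mo (optional piecewise mode fits the 23%/32%/53% milestones at 3/6/12 months) `· (1 + treatment_effect)` while in treatment | effect 0.62 |
| recurrence | `2.36% · 1.16^(episodes−1) · exp(−λ·(t−1)) · (1 − aftercare_effect)` during aftercare | λ = 0.0284/mo |
| death | life-table q(age, sex) `· RR_sex` during diseased months | RR 1.6 (f) / 1.8 (m) |

The recurrence decay factor is anchored at 1 in the first remission month,
so the month-1 values (2.36% after one episode, 2.74% after two) hold for
any λ.  Every hazard is capped at 1 once, after all multipliers, so
parameter sweeps to extreme values remain valid probabilities.

### Event order within a month

The model is defined at monthly resolution, so simultaneous events must be
serialized; the order is fixed and documented because it moves results at
the third decimal: (1) mortality — a death ends the month; (2) diseased:
remission draw (using the current treatment status), then pathway
progression (treatment-month counter with termination at 24 months, waiting
countdown, help-seeking draw); (3) healthy: onset or recurrence draw, then
the aftercare counter (termination at 12 months); (4) age +1.  Occupancy is
the state held at the start of the month: an onset drawn in month *m* makes
month *m+1* the first diseased month.

### The care pathway

Help-seeking is a per-diseased-month probability
`1 − (1 − treatment_reach)^(1/12)`, so `treatment_reach` is the 12-month
cumulative probability of seeking care (33% at status quo; at 100% the first
diseased month already resolves seeking).  A successful seek draws a waiting
time from N(5, 1) months, rounded, truncated at 0.  Spontaneous remission
while waiting cancels the pending treatment — a treatment cannot shorten an
episode that has already ended, which is how the waiting time hurts.
Non-remitters at 24 treated months revert to untreated-diseased and may seek
again (a config lockout disables re-seeking within the episode).  On
remission during treatment the individual enters aftercare with probability
`aftercare_reach`; spontaneous remitters get none.

**Re-treatment policy** (`services.retreatment`): what happens when someone
who was treated before relapses is not an observable of the literature, so
three policies are implemented. `memoryless` restarts seek-and-wait from
scratch; `immediate` puts ever-treated relapsers straight back into
treatment; the default `no_wait` keeps the monthly seeking decision but
skips the waiting queue (the therapist is known, care is established).
`no_wait` is the default because it is the only policy that reproduces the
published scenario results: pure memoryless seeking matches their scaling in
reach but underestimates the treatment endpoints by 3–6 pp, while immediate
re-treatment overshoots the status quo by ~3 pp.

## Demography

A synthetic sex-specific Gompertz–Makeham life table (bundled as
`life_table_default.csv`, yearly rows expanded to monthly hazards) is
calibrated to German-period-table life expectancies, e₀ ≈ 78.6 (m) /
83.4 (f).  The cohort closes at 110 years (q = 1).  Excess mortality
applies multiplicatively during diseased months only.

## Calibrated defaults

Three defaults are not printed values but calibration outputs
(`population_mc.calibrate`: deterministic coordinate search with fixed
evaluation seeds), frozen in `data/defaults_paper.cfg`:

- `course.incidence_scale` (0.16) — sets the absolute level of the
  midlife-peaked onset age profile so that lifetime incidence is 11.4%.
  A flat 1.14%/yr hazard over a full life would give ~57% lifetime
  incidence, so the profile-times-scale construction is what carries the
  age structure.
- `course.remission_decay.rate` (λ = 0.0284/mo) — targets a 54% lifetime
  recurrence fraction among affected individuals.
- `services.aftercare_reach` (0.25) and the `no_wait` re-treatment default —
  chosen jointly so the simulated status quo alleviates ≈9.5% of the burden
  and the treatment reach/effect endpoints land on the published values.
  `services.treatment_effect` (0.62) is back-calculated analytically from
  the printed 71.3% worked example.

## Outcomes

Disease burden = diseased person-months / lived person-months over the whole
cohort, never-ill lives included (a per-affected variant exists behind a
flag).  Burden reduction compares a scenario with the no-healthcare null
(all three reaches 0) run by run: `r_i = (B0_i − B1_i)/B0_i`, reported as
the mean over replicates on the percent scale.  Replicate seeds derive from
`SeedSequence(base_seed, spawn_key=(run,))`, so replicate sets sharing a
base seed share per-run streams; the engine consumes random numbers in fixed
monthly blocks independent of state, which makes the pairing exact common
random numbers — a null compared with itself gives a reduction of exactly 0.

Reported intervals are confidence intervals of the Monte Carlo mean
(mean ± z·SD/√n_runs); a percentile interval over the replicate spread is
available and is the `confidence_interval` default method.

Chronicity follows the pragmatic definition: a course is chronic if any
episode exceeded 24 months or the life had ≥3 episodes.  Episodes truncated
by death count as episodes.

## Simulation sizes

The published study used 1,000 runs × 10,000 lives per scenario.  The test
suite replicates the scenario grid at 100 runs × 5,000 lives (each tolerance
adds the Monte Carlo SE of the scaled run, which common random numbers keep
near 0.1–0.3 pp) and pools the status-quo replicates (500,000 lives) for the
plausibility statistics.  The vectorized engine simulates a cohort
synchronously over ≤1,320 months; one 10,000-life run takes on the order of
a second on one core.

## What the engine does and does not emulate

The cohort is a closed birth cohort under period mortality — no migration,
no cohort trends in incidence or care supply, and services are stationary
over a lifetime.  The synthetic life table reproduces life expectancy, not
the exact German age pattern of deaths.  Passing tests therefore show
internal consistency with the published model world, not forecasts for any
real population.

## Known limitations

- With exponential remission-time decay anchored on the printed 2.36% base
  and 16% per-episode multiplier, hitting the 54% recurrence target forces
  mean episodes per affected ≈ 3.0–3.1 versus the published 2.6; the
  continuation probabilities after later episodes are fully pinned by those
  printed constants.  The published value likely reflects a different
  (unpublished) decay form.  A knock-on effect: the extra short episodes in
  chronic-by-count lives dilute the chronic-class mean episode duration
  (~15.6 months here vs 19.9 published), while the overall mean (14.3–14.5)
  and the non-chronic mean (9.7 vs 9.4) match.
- The "treatment effectiveness = 100%" scenario yields ≈11.4–11.7% burden
  reduction versus the published 12.4%; under the multiplier semantics
  pinned by the 71.3% worked example, episode-shortening algebra cannot
  produce a larger marginal return at 33% reach, so the published
  effectiveness scale presumably differs in the unpublished code.
- The aftercare-effect scenario is over-responsive: setting the aftercare
  effect to 100% yields ≈ +2–3 pp over the status quo here versus +0.1 pp
  published.  Twelve months of full recurrence protection after one quarter
  of treated remissions is simply worth more in this structure; any
  aftercare reach small enough to remove the over-response would also
  undercut the published status-quo reduction.
- The per-life reference implementation and the vectorized engine use
  different random-number layouts; they agree statistically (tested within
  Monte Carlo error), not draw-for-draw.
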