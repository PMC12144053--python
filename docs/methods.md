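# Methods

This note documents the models, rules and numerical choices behind
`sm-phenotype`: what is computed, under which assumptions, and where the
design was genuinely open.

## Episode reconstruction

The app-foreground sensor is a stream of launch instants with no explicit
ends, and sensing pipelines rarely document how they terminate an episode.
Our rules are explicit stand-ins and are stated as such:

- a launch opens an episode for its package;
- the episode ends at the earliest of (a) the participant's next launch,
  (b) the next screen-off or screen-lock event, (c) start + cap;
- the cap defaults to 120 minutes so an unterminated launch (idle phone
  with the screen on, missing screen rows) cannot fabricate multi-hour
  usage;
- "lock" is treated like "off", and "unlock" does not reopen the previous
  app's episode — a deliberately conservative usage estimate;
- consecutive launches of the same package with no terminator between
  them merge into one episode for *duration*, while each launch still
  increments the *checking* count. This reconciles the two features:
  duration measures foreground time, checking counts openings.

All intervals are half-open `[start, end)`, which makes durations exactly
additive across bin boundaries. Timestamps are carried as epoch
milliseconds and converted once, at binning, to local wall-clock time, so
civil dates and hours (00:00–23:59) follow the participant's clock.
Instant→local conversion is total (DST gaps/folds cannot occur in that
direction); naive local timestamp strings, where folds are ambiguous, are
resolved to the earlier UTC offset at parse time.

## Categorization

The packaged key covers the 44 apps of a 2020 adolescent cohort with four
membership flags per package: narrow research-coded social networking
(`sns`, 20), broad research-coded social media (`broad`, 41), the Play
Store's social genre (`google_play`, 26) and survey-defined popular
platforms (`popular`, 9). Two nesting invariants are enforced at load
time (`sns ⊆ broad`, `popular ⊆ broad`); the Play-Store scheme is
independent and contains three apps outside `broad`. Package-name
matching is exact and case-sensitive because Android package ids are
canonical. App functionality drifts, so the key file carries a schema
marker and is intended to be re-issued; `sm-phenotype validate-key`
checks a candidate key's invariants and prints member counts.

Coder agreement over a re-derived key uses Fleiss' kappa for three or
more raters and Cohen's kappa for exactly two; when every cell carries
one identical label, expected and observed agreement are both 1 and the
0/0 ratio is resolved to 1.0 by convention.

## Valid minutes, data yield, and the zero-vs-NA rule

A *valid minute* is a clock-aligned 60-second window (hh:mm:00–hh:mm:59)
in which any sensor logged at least one row. Aligned rather than sliding
windows make the count well defined and additive; a sliding-window
reading of "any 60-second window" would be ambiguous. The *data yield
ratio* of an hour is valid minutes / 60; study-level yield is reported
both hour-weighted (pooled over all enrolled hours) and as the mean of
per-participant ratios, since both conventions are defensible and they
differ when enrollment lengths differ.

Each participant-hour resolves to exactly one of three statuses:

| captured usage | valid minutes | status | value |
|---|---|---|---|
| > 0 | any | `observed` | captured usage |
| 0 | ≥ 30 | `zero_filled` | 0.0 |
| 0 | < 30 | `missing` | NA |

Captured usage is direct evidence the sensing app was running, so it
stands regardless of yield. The 30-minute (50%) threshold is a
researcher-set convention, not a property of the data — it is
configurable (`valid_hour_min_minutes`), and any choice introduces some
bias. Enrollment windows default to [first sensor row, last sensor row]
per participant.

Days aggregate the non-missing hours; hours absent from the enrolled
grid count as missing. A day is excluded from statistics when more than
12 of its 24 hours are missing, mirroring the hour-level 50% convention
(configurable). For per-app tables, day inclusion uses package-independent
missingness (hours under the coverage threshold), so that which app is
being tabulated does not change which days exist; hour-level cells still
honor the usage-overrides-yield rule.

## Features

`sum_duration` apportions each episode to hourly bins by exact interval
intersection; a boundary-spanning episode contributes to both bins.
`count_event` counts a launch once, in the bin containing its start —
an opening is an instantaneous act, and start-bin assignment keeps daily
counts equal to the number of launches. `count_episode` is the 0/1
any-launch indicator. Category cells are sums of member-app cells, which
makes additivity (and the cellwise nesting of narrower schemes inside
`broad`) hold by construction; because one app is in the foreground at a
time, the all-app hourly total can never exceed 60 minutes. Durations are
carried in fractional minutes at millisecond precision; per-app daily
means in sparse cohorts are legitimately far below one minute.

## Statistics

*Variance decomposition.* One-way random-effects ANOVA estimator:
σ̂²_b = (MSB − MSW)/k̄ with the unbalanced group-size correction
k̄ = (N − Σn_i²/N)/(k−1), σ̂²_w = MSW; negative between-components are
truncated to 0 (standard convention). The reported between-fraction
σ̂²_b/(σ̂²_b+σ̂²_w) equals ICC(1,1) on balanced designs, which the test
suite verifies against pingouin.

*Repeated-measures correlation.* x and y are centered within participant
and the centered values correlated; df = N − k − 1 and the p-value comes
from t = r√(df/(1−r²)). This matches the ANCOVA common-slope
formulation (verified against pingouin's `rm_corr`). Participants with
fewer than two complete pairs are dropped — they carry no within-person
information; participants with zero within-variance contribute nothing to
the sums. Policy-excluded days are dropped listwise per analysis.

*Summary blocks* are reported at three grains: between-person (average
within participant first), daily, and hourly. Hourly blocks include
zero-filled bins — they do not exclude hours when adolescents were asleep
or simply not on their phone; the block carries an `includes_idle_hours`
caveat flag rather than silently filtering.

## Synthetic cohort generator

The generator emulates a month-long adolescent sensing study and is the
oracle for every downstream stage. Structure:

- **Two-level daily targets.** Participant i draws a true mean daily
  duration μ + b_i, b_i ~ N(0, between_sd²); day t realizes
  μ_i + e_it, e_it ~ N(0, within_sd²); both truncated at 0. Checking
  counts follow the same structure, and (duration, checks) day deviations
  are jointly normal with correlation ρ (`duration_checks_rho`). A day
  whose check target rounds to zero while its duration target is positive
  gets one launch (usage implies an opening); a day with nonpositive
  duration target gets no usage rows.
- **Within-day placement.** Launch hours are drawn from a 24-bin diurnal
  profile (default: low overnight, evening peak); session lengths are
  heavy-tailed (log-normal weights) capped at 120 minutes and rescaled by
  water-filling so the day's total matches its target exactly up to
  capacity; sessions never overlap (one foreground app at a time) and a
  ~0.3 s guard gap separates back-to-back sessions. Each session emits a
  screen-on row at its start and a screen-off row at its end, so episode
  reconstruction is exact and recovered daily sums match the generator's
  ground truth to well under 0.1 min.
- **Auxiliary sensor.** One row per clock minute with uniform jitter
  inside the minute (plus optional extra rows), making valid-minute
  ground truth exact: with no outages every enrolled hour has 60 valid
  minutes.
- **Outages.** Poisson-count intervals per participant with log-normal
  lengths; *all* sensor rows inside an outage are deleted — usage during
  an outage is unobserved, exactly as when the sensing app crashes.
  Overlapping drawn intervals are merged so schedules are disjoint.
- **Determinism.** One root seed spawns an independent child stream per
  participant; identical (config, seed) reproduce byte-identical tables.

Default parameters emulate the regime such studies report: 19
participants × 31 days; mean daily broad-social-media duration 95 min
with between-SD 62 and within-SD 50 (total daily SD ≈ 79.6, between
fraction ≈ 0.61); 160 daily checks with between-SD 120 / within-SD 85
(between fraction ≈ 0.67); duration–checks coupling ρ = 0.55; and an
outage load (2.5 episodes/participant/day, log-normal lengths with median
90 min) producing roughly 25% downtime and a study yield ratio in the
mid-70% range. All instants are generated in a DST-free zone
(`America/Phoenix`) so calendar pathologies cannot leak into binning
tests; DST handling is exercised separately in ingest tests.

What the generator does **not** emulate: app content and notifications,
participant-specific compliance behavior (outages are homogeneous
Poisson, so per-participant yield varies less than in real cohorts),
multi-device usage, weekly rhythms, and any mental-health outcome
process. Passing recovery tests therefore show the *pipeline* measures
what was put in — not that real adolescent data satisfy the generative
model.

### Calibration regime

At realistic (study-scale) parameters the truncation at zero is material
— about 6% of drawn person means fall below zero — which attenuates the
realized between-person variance fraction below the configured value.
Parameter-recovery runs therefore use a cohort whose grand means sit more
than four SDs above zero (300 min/day duration, 60 checks/day), where
truncation mass is negligible and the configured fraction (exactly 0.60)
and coupling (0.55) are realized: 40 participants × 200 days, run through
the *full* pipeline (events → episodes → bins → features → statistics).
The yield calibration deletes each sensor row of a usage-free 19 × 31
cohort independently with probability 0.25; with one row per minute this
makes each minute invalid with probability 0.25, so the expected study
yield is 0.75 with a binomial standard error. These problem sizes keep a
complete calibration run under a minute on one CPU.

## Numerical choices and degenerate inputs

- Hourly feature cells agree with a per-second brute-force accumulator to
  ~1e-14 minutes; the residual is float summation order (several episode
  segments per cell versus one division), not method error.
- Duplicate sensor rows are dropped with a logged count; zero-length
  episodes (two launches at the same instant) are dropped for duration
  but their launches still count.
- Degenerate statistics raise rather than return conventional values:
  single-participant ICC, all-degenerate rm-correlation inputs, empty
  summaries. The one convention is kappa = 1.0 under a single observed
  label.
- Configuration errors name the offending field.

## Known limitations

- The episode termination rules are documented stand-ins; real pipelines
  may differ, and no ground truth exists to arbitrate.
- Whether a published study's yield figure is hour-weighted or
  participant-weighted is often unstated; both are emitted and neither is
  privileged.
- The within-person coupling ρ applies to day-level deviations; the
  generator does not model hour-level coupling.
- The per-app table's "all participants" variant treats participants with
  no usage of an app as zero-mean contributors, which is only meaningful
  when their days were otherwise observed; day inclusion is
  package-independent by design.
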