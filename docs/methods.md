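# Methods

This note documents the models and procedures `actihf` implements, the
choices made where a processing convention was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Signal model and processing chain

A wrist-worn triaxial accelerometer measures acceleration in mg
(1 g = 1000 mg).  At rest the vector norm is gravity; movement intensity is
quantified by ENMO, `max(0, ||(x, y, z)|| − 1000)` mg, averaged over 5-s
epochs.  Negative values (possible through calibration error) are truncated
at zero: that is the established ENMO convention, and without it the
inactivity cut-points below would misbehave on idle signal.  Epoch
boundaries are aligned to multiples of the epoch length counted from local
midnight so that days are exact 17,280-epoch blocks.

**Autocalibration.**  Gains and offsets drift per device; stationary
periods provide calibration points that should lie on the 1 g sphere.  A
10-s window with all three axis SDs below 13 mg is treated as stationary;
if at least 20 such windows span at least 6 orientation octants, per-axis
gain and offset are fitted by iterated least squares toward the nearest
point on the sphere (the standard sphere-calibration approach).  With fewer
windows or orientations the fit is not identifiable and calibration
degrades to a logged no-op.  Fitted gains outside [0.9, 1.1] or offsets
outside ±150 mg are considered implausible for a working device and are
not applied.  The procedure is idempotent on calibrated data.

**Artifacts.**  Samples with vector norm above 8000 mg (the typical range
limit of wrist devices) flag their epoch, as do epochs with no samples.
Artifact epochs count as non-wear for day-validity purposes.

**Non-wear.**  A 60-min window slides in 15-min steps on the
midnight-anchored grid; if at least 2 of the 3 axes have range < 50 mg and
SD < 13 mg within the window, the device is judged off-body.  The rule
gives window and step sizes but not which epochs to mark; marking the
*central 15 min* of each qualifying window was chosen because marking whole
windows over-flags the worn edges of long still periods, while the union of
central blocks converges to the same interior.  Streams shorter than one
window produce no flags (logged).  An exhaustive per-window oracle
reproduces the detector exactly in the test suite.

**Valid week.**  A calendar day is valid when fully covered by epochs and
carrying at least 16 h of wear; analysis uses the earliest run of 7
consecutive valid days.  Partial first/last days are never valid.  Days are
midnight-to-midnight in the configured timezone; the default is UTC (or any
fixed-offset zone) because a DST transition makes a civil day 23/25 h and
would violate the exact-day epoch count.  This is a known limitation for
DST zones; for trial data recorded in one country the fixed-offset
approximation shifts day boundaries by at most an hour for part of the
wear week.

## Intensity metrics

Heart-failure-specific cut-points (mg): inactivity < 16.7 (left wrist) /
18.6 (right); MVPA >= 43.6 (left) / 45.5 (right).  Boundary handling
mirrors the MET definitions: inactive is strictly below the inactivity
cut (< 1.5 METs), MVPA is at or above the MVPA cut (>= 3.0 METs), light is
the band between.

**Non-wear imputation.**  Daily totals must close the 1440-min day, so
non-wear/artifact epochs are imputed with the mean ENMO of worn epochs at
the same clock time on the other days of the week (same-subject circadian
profile), falling back to 0 mg when no day is worn at that time.  Wear
time is always computed from the original flags.

**Bouts.**  A bout is a sustained period of >= 10 min in one category with
up to 20% of epochs outside it; its first and last epoch must be
in-category.  Bout selection scans left to right: the leftmost epoch that
can start a feasible bout starts one, the end is the *longest* feasible
in-category end, and consumed epochs are never reused, so accepted bouts
are disjoint and ordered.  These semantics are frozen by a brute-force
reference oracle (full enumeration of candidate index pairs with greedy
leftmost-longest acceptance) that the fast implementation — a prefix-sum
transformation with a suffix-maximum search, O(n log n) — must match
exactly on randomized fixtures.  Bout minutes count *all* epochs inside an
accepted bout, including allowance epochs: the bout is the behavioural
unit, and per-category bouted totals are reported separately, never summed.
The fraction comparison uses a 1e-9 slack on an integer-count inequality,
far below the 1/length granularity of true fractions, so ties at exactly
20% are accepted deterministically.

**Daily and weekly summaries.**  Unbouted minutes per category are epoch
counts times epoch length; the three categories partition the 17,280-epoch
day exactly (minute values carry only the binary representation error of
count/12).  Weekend days are Saturday and Sunday of the local calendar.
The all-days mean is the (5 x weekday + 2 x weekend)/7 weighted mean;
weekly MVPA is 7 x the all-days mean and sets the >= 150 min/week
guideline flag, computed for bouted and unbouted accumulation separately.

## Trial statistics

**Intervention effects.**  For each outcome (3 intensities x all
days/weekdays/weekend days, bouted or unbouted), the follow-up value is
regressed on its baseline value, the group indicator (intervention = 1),
the NT-proBNP >= 2000 pg/mL stratum and centre (OLS; normal-theory 95% CI;
two-sided p).  Centre coding is configurable: indicator coding (first
centre as reference) is the default for the outcome table; the predictor
models default to a single ordinal centre covariate, matching the
single-coefficient presentation they replicate.  Constant nuisance
covariates are dropped with a log note; an aliased requested term (e.g. a
single-arm dataset) raises an estimation error naming the term.  Guideline
attainment uses the analogous logistic model; detected separation (fitted
probabilities pinned at 0/1) flags the estimate rather than trusting it.

**Predictor models.**  Candidate baseline covariates are screened one at a
time, each adjusted for baseline MVPA, group, stratum and centre, with
entry at p < 0.15 and complete-case handling per candidate (zero-variance
or under-populated candidates are skipped with a warning).  Model 1 fits
the socio-demographic/medical-history survivors, model 2 the exercise-
capacity/health-status survivors, and model 3 the p < 0.05 survivors of
models 1 and 2 — requesting model 3 first is a sequencing error.  Each fit
reports coefficients with CIs, adjusted R², AIC, per-predictor VIF and
per-observation Cook's distances; observations above the flag threshold
(default 4/n) are reported, never silently removed.  p values are
two-sided and uncorrected, reflecting the exploratory design of such
analyses.

## Synthetic-data generator

The generator's defaults are the study conditions of the trial it
emulates: two arms (122/125 enrolled, retention 198/247 and 173/247 at
the two follow-ups, analysed arms 80/93), 24-h wear protocol over 9 days
starting on a Monday, and arm-level activity summaries per day type and
visit frozen in `actihf.presets`.

Per subject, daily bouted MVPA and light-PA volumes are lognormal
(right-skewed, matching the large SDs of wrist accelerometry in this
population) with mean/SD matched to the arm summaries; baseline and
follow-up share a latent normal with correlation 0.5.  Day-to-day
variation is a mean-one lognormal multiplier (CV 0.35 for MVPA, 0.20 for
light).  Short-burst activity (3-min MVPA, 5-min light blocks) adds
unbouted-only minutes at fixed fractions of the bouted targets.  Inactive
time is the complement of the 1440-min day.  Extreme days are capped 45
min below the wake budget so scheduling (and injected shifts) stay
feasible.  A covariate model, used by the `table3` preset, replaces the
follow-up MVPA draw with baseline + a linear covariate-driven change
(residual SD 54 min/day, chosen so the combined model explains roughly
15% of change variance, consistent with the reference model fit).

Three fidelities share this ledger: `plan` (per-day minutes only,
vectorised — used for replicate studies), `epoch` (behaviour-block
schedules realised as lognormal 5-s ENMO epochs; sleep 3 mg, sedentary
8 mg, light 28 mg, MVPA 85 mg by default, every state mean validated
against its intensity band) and `raw` (triaxial samples whose norm is
1000 mg + the epoch level, with a slow orientation random walk during wear
and a frozen orientation during non-wear so the non-wear detector sees
realistic contrast).  `inject_compensation` shifts an arm's follow-up
weekday/weekend minutes by fixed deltas with ground truth updated,
enabling end-to-end verification that the pipeline detects weekday gains
alongside weekend losses.

Replicate-based estimator studies (bias of the ANCOVA effect, type-I
error, CI coverage) use outcome-level simulators
(`simulate_ancova_cohort`, `simulate_guideline_cohort`,
`simulate_predictor_cohort`) that generate the regression's inputs
directly under the stated scenario — arm sizes 80/93, the reference
baseline/follow-up SDs, correlation 0.5 and a common-slope construction in
which the generating group effect is exact.  Signal-level generation of
hundreds of full trials would add nothing to those checks but orders of
magnitude of runtime; the signal path is instead verified by closed-loop
tests (noise-free days recover their minute ledger exactly; a noisy 30-min
MVPA block is recovered within ±2 min, the epoch-edge tolerance).

**What passing tests do not show.**  The generator reproduces summary
moments, skew, within-subject correlation and the bout/non-wear structure,
not physiological waveforms, circadian detail beyond the scheduled blocks,
posture-specific calibration error, or informative missingness (attrition
and non-wear are missing completely at random here).  Agreement on
synthetic data therefore validates the arithmetic and the estimators under
the stated generating model, not device behaviour in the field.

## Problem sizes and numerical choices

The test suite runs 500-replicate recovery studies for the two weekday
effects, 1,000 null replicates for type-I error, 1,000 random fixtures
(up to 2,000 epochs) for the bout oracle, exhaustive-scan comparison on
mixed fixtures up to 12 h for non-wear, and 200 replicates at n = 170 for
predictor-coefficient coverage — sizes at which Monte-Carlo error is small
relative to the tolerances tested.  Tolerances: 2 Monte-Carlo SEs for
recovery means, the 3.7–6.3% binomial band for type-I error at 1,000
replicates, exact interval equality for both oracles, 1e-9 min for
day-closure identities, and one unit in the last printed digit (0.01)
when comparing change scores recomputed from rounded summary means.
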