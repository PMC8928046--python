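# Methods

## Measurement model

The unit of measurement is the 1-minute epoch. A participant-week is 7
consecutive calendar days of 1440 epochs each, carrying METs, energy
expenditure (kcal/min), steps and a wear flag. Energy bookkeeping
anchors 1 MET to the participant's measured resting metabolic rate
(RMR): a minute at m METs costs m·RMR/1440 kcal, so PAL (total energy
expenditure divided by RMR) equals the day's mean MET value. This same
anchoring is used for non-wear imputation (a missing minute is assigned
1 MET, RMR/1440 kcal, 0 steps) and for the personalised energy cost of
planned activities.

Intensity classes partition [0, ∞) with half-open MET bounds:
sedentary [0, 1.8), light [1.8, 3.0), moderate [3.0, 6.0), vigorous
[6.0, ∞). Boundary values belong to the class they open.

### Waking window and validity

The waking day is a fixed, configurable clock window, 07:00–23:00 (16 h
= 960 min) by default. Three consequences, all deliberate:

* the 80% valid-day wear criterion is evaluated against the waking
  window only (768 of 960 minutes); wear outside it is ignored;
* sedentary percentage uses the full 960-minute imputed window as its
  denominator, keeping days comparable regardless of wear;
* imputed minutes (1 MET) count as sedentary in class tallies but stay
  identifiable through the `imputed` flag.

A week is valid with ≥ 6 valid days; invalid weeks are excluded from
analysis and logged with a reason, never silently dropped. Sub-minute
input is rejected rather than resampled.

### Bout detection

Bouted MVPA (≥ 3 METs) and bouted vigorous activity (≥ 6 METs) sum the
lengths of maximal runs of consecutive qualifying minutes that last at
least 10 minutes, with strict contiguity: a single sub-threshold minute
ends the run, runs are cut at day boundaries, and an entire qualifying
run counts (a 23-minute run contributes 23 minutes). Strictness is the
minimal reading of "accumulated in bouts of ≥ 10 minutes" and is
exactly checkable against a brute-force run scan, which the test suite
does on 1000 random minute vectors. An interruption tolerance
(merging runs separated by short sub-threshold gaps) exists as a knob
and defaults to 0.

## Trial statistics

The estimand per outcome and follow-up week is the adjusted mean
difference (intervention − control) from the linear model
`follow_up ~ group + baseline + sex + weight_status`, the covariates
being the baseline value of the outcome and the two stratification
factors of the randomisation (sex; BMI ≥ 30 as binary weight status).
The model is fit by least squares in-package (the bootstrap needs ~10⁶
refits; statsmodels OLS is the independent cross-check in tests and
supplies the HC3 heteroscedasticity-robust SE reported alongside, our
operationalisation of "accounting for unequal variance under unequal
allocation"). Constant covariates are dropped with a warning.

Confidence intervals use the bias-corrected and accelerated (BCa)
bootstrap, default 5000 replications: participants are resampled with
replacement *within arm* (preserving the 36:15 allocation),
z₀ = Φ⁻¹(proportion of bootstrap statistics below the observed value,
ties counted half), and the acceleration is the jackknife skewness
a = Σ(θ̄−θᵢ)³ / (6[Σ(θ̄−θᵢ)²]^{3/2}). A degenerate bootstrap
distribution returns a point-mass interval with a warning. Effect sizes
are Hedges g: the adjusted difference over the follow-up SD pooled
across arms, times J = 1 − 3/(4(n₁+n₂−2) − 1); the pooled follow-up SD
(not the baseline or residual SD) is a declared convention. One
stratified bootstrap drives both the difference CI and the g CI.

Subgroup descriptives report unadjusted mean (SD) cells by sex or by a
median split of baseline PAL (ties to the low group). The eligibility
screen excludes participants with baseline PAL ≥ 2.0 (already highly
active); the pipeline exposes it but does not apply it to the default
synthetic cohort, which is calibrated to an already-enrolled (screened)
population.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable without
raw trial data. It emulates the measurement regime — two arms of 36 and
15, three 7-day assessment weeks, minute-level device output with wear
gaps — with group-level dimension distributions calibrated from printed
summaries (mean and 95% CI per arm/week cell; between-person SD
recovered as (CI_hi − CI_lo)/(2·z₀.₉₇₅)·√n).

**Programmed effects.** The default configuration equalises the arms at
baseline and week 6 (pooled printed means) and programs the week-12
intervention mean as the printed control mean plus the printed
*adjusted* difference. This makes the true adjusted difference known
exactly — chance baseline imbalances in the printed cells would
otherwise leak through the ANCOVA's baseline adjustment — and, because
the printed summaries are internally consistent, the implied week-12
intervention means still sit within one unit of their printed cells.

**Channel structure.** The bouted dimensions are nested (vigorous ≤
MVPA ≤ 7 × daily moderate minutes), so the generator draws structural
channels — vigorous bout minutes, moderate bout minutes (MVPA −
vigorous) and unbouted moderate minutes (7·moderate − MVPA) — with
variances derived by subtraction. Means are preserved exactly; a
negative variance difference (one week-6 cell) floors the derived SD at
zero. Non-negative channels are drawn as *rectified* normals whose
location is solved so the rectified mean equals the calibrated mean;
without this, clipping at zero would inflate low-mean/high-SD cells
(vigorous bouts especially) differently in the two arms and bias the
programmed differences. A person-level random effect shared across
assessment weeks (correlation 0.7) gives participants stable
activity levels, which is what makes baseline adjustment informative.

**Minute rendering.** Each day places a sleep block at 0.9 METs outside
the waking window; vigorous and moderate bouts cut into 10–60-minute
runs (truncated geometric lengths, totals conserved exactly above 10
minutes; totals below 10 become a single 10-minute bout with the
probability that preserves the mean); unbouted moderate minutes
scattered as 1–9-minute runs; at least one sub-threshold minute
separates consecutive activity runs so rendered bouts are exactly the
drawn bouts. Remaining waking minutes split into sedentary and light
filler whose within-band MET levels are solved so the day's mean MET
equals the PAL draw; if the filler bands cannot carry the energy
budget, the excess spills onto the activity-run minutes within their
own class bands instead of being clipped. Steps follow cadence bands
(light 60–89, moderate 90–119, vigorous 120–140 per minute) rescaled to
match the drawn daily step total exactly. Day-to-day variation defaults
to 10% of the cell mean (for PAL, 10% of the activity margin above 1);
the source summaries give no within-person variance, so this is a
configuration default, not a reconstructed study value.

**Wear gaps.** By default one gap per day (Poisson), mean length 15
minutes (exponential), placed uniformly in the waking window — about
99% 24-hour wear, matching the high compliance such protocols report.
Gap minutes are imputed at rest downstream, which shrinks activity
dimensions slightly in *both* arms (≈ 1–3% of a between-arm
difference); the recovery tolerance accounts for this.

**What the generator does not emulate.** Raw sensor signals, activity
type structure, weekday/weekend rhythms, correlations *between*
dimensions beyond the structural nesting, dropout (none is simulated),
or device error. Passing closed-loop tests therefore demonstrates that
the pipeline's computations and statistics are correct and unbiased
under the modelled data-generating process, not that the device or the
original study's estimates were accurate.

## Calibration evidence and known limitations

* Closed-loop recovery (200 replicate trials through the full minute
  pipeline in the test suite, 300 in the acceptance script): the mean
  recovered week-12 adjusted difference matches the
  programmed effect for all five headline dimensions within 3
  Monte-Carlo SEs plus the 5% gap-shrinkage allowance; the acceptance
  script reproduces this from scratch.
* Null calibration: with identical arms, classical OLS intervals for
  the adjusted PAL difference reject in 4.2% of 2000 replicates — the
  generator's null is clean.
* Known limitation: the BCa interval itself over-rejects at this sample
  size. With 15 participants in the control arm it rejects a true null
  in ≈ 6.8% of replicates (and ≈ 7.7% for a textbook normal mean at
  n = 15) — the documented small-sample anti-conservatism of
  nonparametric bootstrap intervals. The type-I acceptance test pins
  the nominal 5% ± 1.5% band and is expected to fail until a
  small-sample correction is adopted; the companion OLS check shows the
  excess belongs to the interval, not the generator or the estimator.
* Problem sizes: the default suite uses 200 recovery replicates, 2000
  null replicates at 999 bootstrap replications, and a 14-participant
  cohort for end-to-end I/O tests; one full 51-participant trial
  (simulate + process + profile) takes ≈ 0.6 s, and a full analysis
  with 5000-replication BCa intervals ≈ 13 s.
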