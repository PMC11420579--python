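# Methods

`alarmkit` analyzes patient-monitor alarm logs from intensive-care
units.  The scientific question it serves is whether alarm exposure —
and with it the risk of alarm fatigue — differs systematically between
two kinds of units (in the motivating setting: provisionally converted
COVID-19 ICUs versus regular surgical/medical ICUs).  This note
documents the models, the parameter choices, the synthetic-data
generator, and the numerical conventions in enough detail that a
maintainer can judge what a passing test does and does not demonstrate.

## Event model and conventions

Alarm, pause, and settings-change events carry a unit, bed, timestamp
(timezone-naive local time, second resolution), and for alarms a
duration in seconds, a device (ECG, IBP, NIBP, SpO2, temperature,
other), a color class (red = potentially life-threatening, yellow =
threshold crossing, technical = sensor/device condition, blue =
advisory on some monitor configurations), and a free-text signal label.

Conventions, chosen once and applied everywhere:

* A calendar day runs midnight to midnight; an event straddling
  midnight is attributed **entirely to the day of its onset**.  This is
  the simplest convention that keeps per-day tallies conservative; at
  realistic alarm durations (seconds to minutes) the distortion is
  negligible.
* Seconds are half-open intervals `[onset, onset + duration)`; an alarm
  of duration 0 occupies no full second.
* BLUE alarms stay in the data model (the ECG-lead-off signal is
  classified inconsistently across monitor configurations and must be
  traceable) but are excluded from all load contrasts by default.
  Lead-off events are *flagged*, not dropped, so the yellow-load
  contrast can exclude them while technical tallies retain them.
* Ventilator alarms are removed wholesale during harmonization: in the
  motivating data they were unreliably transmitted to the log, so any
  count involving them would be biased.  Every removal is tallied by
  rule, and `events_in = events_out + Σ removals` holds by
  construction.

## Metric suite

All rates are **per occupied bed per day**: the unit-day tally divided
by beds occupied that day.  A unit-day with events but zero occupied
beds is an inconsistency; its rate is *undefined* (not zero), the row
is flagged and excluded from downstream statistics.

**Alarm flood episodes.**  A flood is ≥ 10 alarm onsets within 10
minutes, counting only red and yellow (auditory) alarms.  The detector
slides a 600 s window anchored at each onset within one bed's daily
stream; overlapping qualifying windows merge into a single episode.
Sliding windows avoid the boundary artifacts of fixed bins, and per-bed
detection matches per-bed-per-day reporting; a unit-level variant is
available by flag.  The detector is validated against an O(n²)
all-pairs-window oracle on random instances.

**Concurrent alarm duration.**  For every second, the contribution is
`max(0, active_alarms − 1)`: two simultaneous alarms add one concurrent
second per second of overlap, three add two.  Durations above 1800 s
are outliers and excluded *before* accumulation.  Concurrency is
computed across the whole unit by default — alarms from different beds
ring in the same soundscape, and the metric models staff sound
exposure — with a per-bed variant by flag.  The change-point sweep is
validated against a literal per-second oracle.

**Pause metrics.**  Pause activations per bed per day, plus the
*proper pause-to-pause ratio*: the fraction of pauses judged
appropriately used.  The bedside definition of "proper" is not
published, so the predicate is pluggable; the shipped default counts a
pause as proper when at least one alarm onset on the same bed falls
inside the pause window — i.e. the pause actually suppressed sound.
This is an interpretation, stated as such.

## Inferential battery

All tests are one-sided (the prior hypotheses state a direction:
isolation units above general units) at α = 0.05, Bonferroni-adjusted
within each hypothesis family (family size = number of subtests, e.g. 4
color strata for the load family).

**Gamma GLM on loads.**  Per-unit-day loads are right-skewed and
approximately gamma; group means are compared with a no-intercept
log-link gamma GLM with one indicator per group (statsmodels).  This
model is saturated in the group factor, so `exp(coef_g)` equals the
group sample mean exactly — an identity asserted on every test fixture
— and the contrast is a one-sided Wald test on the log scale.  Zero
loads violate the gamma support; they are rejected, or excluded with a
logged count when explicitly enabled.

**Bootstrap margin test on duration medians.**  At five-to-six-figure
alarm counts any difference is "statistically significant", so the null
is `median_a − median_b ≤ 3 s`: a difference must exceed a practical
margin to count.  The test statistic is the raw median difference; each
group is resampled with replacement (default B = 10 000, blockwise to
bound memory), and the bootstrap distribution is recentered at the
margin (shift-to-boundary calibration) to yield a percentile p-value.
This is the standard one-sided bootstrap construction for a composite
null; simulation at the boundary (true difference exactly 3 s)
reproduces the nominal 5% rejection rate within Monte-Carlo error.

**Median-based d-type effect size.**  For duration contrasts the effect
size is `(median_a − median_b) / s_pool` with `s_pool` the pooled SD of
the raw observations, and variance `(π/2)(1/l_a + 1/l_b)·k̄` where
`l` are alarm counts, `k̄` the mean number of contributing units
(a design-factor inflation: alarms from one unit are not independent),
and π/2 the asymptotic efficiency factor of the median.  **This
estimator is a reconstruction**: the published formula body was not
available, so it is validated only for sign, zero on identical samples,
antisymmetry under group swap, variance monotone decreasing in the
alarm count, and order of magnitude (d-type values of order 10⁻² for
second-scale median gaps against minute-scale raw spreads).

**Cohen's d and the t test.**  Standard pooled-SD Cohen's d for load
and fatigue contrasts, with a from-summary variant so printed
mean/SD/n triples can be checked directly.  The fatigue comparison uses
Welch's unequal-variance t test (the motivating analysis reports
fractional degrees of freedom, which identifies Welch).

## Questionnaire scoring

Nine Likert items coded −2…+2 ("partly agree" = 0).  Four items are
reverse-worded and negated before summation; the published short form
does not identify them, so the set is configurable (shipped default:
items 2, 4, 6, 8) and every scoring property holds for any 4-element
set.  The sum is the fatigue score in [−18, 18]; the reported
percentage is the linear map `(score + 18)/36 × 100`, which is the
unique affine map sending the documented endpoints to 0/100 and the
documented midpoint to 50.

Responses missing 1–2 items are completed by single-draw predictive
mean matching: each missing item is OLS-regressed on the recipient's
observed items over the complete responses, and the imputed value is
drawn from the 5 donors with nearest predicted means — hence always a
value some donor actually gave.  Responses missing ≥ 3 items are
excluded with a reason code, never imputed.

## Synthetic-data generator

No public alarm-log data exist for this setting, so the generator is a
first-class, tested component whose defaults encode the study
conditions: 113 days, two general units (surgical/medical) versus two
isolation units, per-unit gamma daily loads and occupancy fractions set
to the published per-unit means/SDs, exponential durations matched to
the published medians, pause rates 12.21 vs 5.08 per bed-day, and
questionnaire groups at the published percentage means (clinicians
59.00/13.05 vs 64.28/14.20; support-staff means back-solved from the
overall group means).  Bed capacities are not published; the presets
use 16/14 beds for the general units and 16/12 for the isolation units,
a typical scale for the setting.  Settings-change rates are likewise
unpublished (reported only graphically); defaults of 1.5/0.3 (general)
and 0.8/0.15 (isolation) threshold/profile changes per bed-day were
fixed once as plausible and are not calibration targets.

Structural choices:

* **Occupancy** follows a bounded random walk around the unit's mean
  fraction, clipped to [0.3, 1]; daily counts are rounded and kept ≥ 1.
* **Daily counts** are gamma-then-rounded (`round(load × beds)`);
  onsets are uniform within the day.
* **Flood structure** comes from a burst knob that *reallocates* part
  of the yellow pool into clusters (default 12 onsets within 300 s on
  one bed) at the unit's published flood rate — reallocation, not
  addition, so configured loads are preserved.  Real alarm streams'
  inter-arrival structure is uncharacterized; the burst model is
  synthetic-only structure and is labelled as such.
* **Durations** are exponential truncated at 7200 s so the 1800 s
  outlier rule is exercised.  Real duration distributions are heavier
  tailed than exponential at matched medians; consequently the
  generator's absolute concurrent-duration levels sit well below the
  published per-bed values even though every *relative* contrast
  (group ordering, ratios) is preserved.  Passing pipeline tests
  therefore demonstrate correct accounting and ordering recovery, not
  absolute concurrency realism.
* **Pauses**: with probability `proper_pause_prob` a pause is placed
  bracketing an alarm onset (proper use); otherwise it is
  rejection-sampled into an alarm-free stretch on its bed, modelling a
  pause that suppressed nothing.  Realized proper ratios then track the
  configured probabilities up to chance coincidences.
* **Questionnaire items**: each respondent draws a latent percentage
  from the group normal, converted to a per-item success probability;
  items are `Binomial(4, p) − 2`, so the 9-item sum recovers the latent
  score in expectation.  Binomial thinning adds item-level noise and
  mildly attenuates standardized effect sizes — recovery tests allow
  for this.

A known divergence of the source tables themselves: the published
per-unit color means do not sum exactly to the published per-unit
totals, nor exactly to the pooled group means (discrepancies up to
~5%).  The presets take the per-unit color means verbatim; implied
totals therefore differ slightly from the pooled figures, and tests
compare pooled totals at 6% relative tolerance.

## Problem sizes and numerics

Statistical validation runs at the sizes the design states: gamma-GLM
recovery at n = 113 unit-days per group over 100 seeded replicates;
bootstrap boundary calibration over 500 replicates at B = 2000 with
n = 400 durations per group (large enough that the median's bootstrap
distribution is effectively continuous); oracle equivalence on 200
random instances per algorithm.  Pipeline-level tests use scaled-down
scenarios (12–30 days) — scale affects only Monte-Carlo precision, not
any code path.  Bootstrap resampling is blockwise (≈2 × 10⁶ index
entries per block) to bound memory; every stochastic routine takes an
integer seed or `numpy` Generator and is bit-reproducible under it.

## Limitations

* The median-based d-type effect size and the fatigue percentage map
  are reconstructions anchored to documented endpoints, not verified
  formula bodies.
* The reverse-item set and the "proper pause" predicate are explicit
  interpretations, both configurable.
* The generator emulates marginal distributions and first-order rates;
  it does not model within-day nonstationarity (shift changes, rounds),
  patient-level correlation, device co-alarming, or heavy-tailed
  durations, so absolute flood and concurrency levels on real data will
  differ from synthetic levels even at identical configured loads.
* Real exports require a user-supplied column/element dialect; the
  shipped label→(device, color) mapping covers the commonly named
  signals only, and unmapped labels fall back to OTHER with a warning.
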