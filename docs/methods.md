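# Methods

## The monitoring model

`ratwelfare` models the weekly welfare and physiology monitoring of a
two-arm rat study: a control arm (n = 8) and an induced arm (n = 16)
that drinks 10 % fructose during protocol weeks 1–2 and receives a
single 40 mg/kg i.p. streptozotocin injection at the end of week 2.
The protocol runs 7 weeks (49 days); weeks are 1-based, week 1 being
the first fructose week.

### Welfare rubric and decision rules

The rubric is a fixed table of 14 ordinal parameters. Each parameter
admits only the levels for which a clinical descriptor exists — the
gaps are deliberate (Posture {0,1}, Walk {0,3}, Convulsions {0,3},
Hydration {0,1}, Stool {0,1,2}, the abdominal item {0,1,2}) — and a
level outside the admissible set is a hard validation error, never
clamped. The maximal valid total is 33.

Decision semantics: a weekly total of 4 triggers a critical
re-evaluation; five specific observations (weight loss > 20 %, severe
anaemia/corneal ulcers, walking on the tip of the extremities, skin
necrosis, stupor/coma) indicate euthanasia regardless of the total. The
engine reports `EUTHANASIA_INDICATED` and leaves the final disposition
to the veterinarian: the printed protocol itself requires re-evaluation
before sacrifice. Convulsions (level 3) and a violent response to
stimuli are *not* euthanasia-marked — they carry no such marker in the
rubric table — so they contribute to the total only. This is a
deliberate literal reading; a laboratory adopting the package can add
markers in its own rubric JSON.

Two boundary conventions are fixed: the skin-pinch dehydration test is
strict ("more than 2 s", so exactly 2.0 s is normal), and a weight loss
of exactly 20 % scores level 2, with level 3 beginning strictly above
20 %.

Three observers score each animal weekly. The combination rule is not
part of the printed protocol, so the package chooses: the per-parameter
**median** of three observers (no ties possible), the **maximum** of
two (conservative for welfare), identity for one. Both the per-observer
and the consensus series are exposed.

### Physiology calculators

The body-weight-gain formula normalises by the *current* weight,
`(current − initial)/current × 100`. This is unconventional (the usual
denominator is the initial weight) but it is the formula the protocol
prescribes, so it is the default; `denominator="initial"` selects the
conventional variant.

The Lee index is implemented verbatim as `weight / NAL³` (units
g/cm³). Published rodent tables often report Lee-index values near
2–3, which corresponds to `(weight^(1/3))/NAL × 1000` — a different
formula. The two are not reconcilable by a constant factor across
groups, so the package evaluates the printed ratio and exposes an
explicit `scale` multiplier; no claims are made about reproducing
tabulated Lee values, and the discrepancy is intentional and
documented here.

Glucometer censoring: the meter tops out at 600 mg/dL. "HI" readings
(and, tolerantly, any numeric input above 600, which a real meter
cannot emit) are recorded at 600 and flagged censored. Group summaries
over all-censored readings therefore give 600.00 ± 0.00. Outlier
flagging uses Tukey boxplot fences with linear-interpolation quartiles
(the numpy `method="linear"` convention, identical to the stdlib
`statistics.quantiles(method="inclusive")`), fixed so tests are
bit-stable.

Water consumption is accounted two ways, matching a mid-study protocol
change: weekly bottle weighing (like food) through week 3, and a single
24-h cage total divided by the cage occupancy from week 4 onward, when
polydipsia made weekly accounting unreliable.

### Statistics

Longitudinal measures use an ordinary two-way ANOVA (group × week) on
the tidy per-animal table. The per-week group contrast uses the pooled
residual mean square of the full factorial cell-means fit with its
residual degrees of freedom — the convention of standard ANOVA
post-tests — and the raw p-value is Šidák-adjusted for the number of
weeks (`p' = 1 − (1 − p)^m`). Endpoint measures use the classic
pooled-variance Student t-test (Welch available by option). Ordinal or
non-normal endpoints — in practice the per-animal maximum weekly
score — use the Mann-Whitney U test: exact when the combined sample is
at most 20 and tie-free, otherwise the normal approximation with tie
correction. Fully tied degenerate data yields p = 1 by convention.
Sample SD uses n − 1, with a singleton's SD reported as 0 to match the
"± 0.00" table style.

## The synthetic-cohort generator

The generator emulates the study conditions so the whole pipeline can
be exercised and calibrated without animals. Its defaults are the
study's own endpoint and event statistics; they are constants of the
emulation, not tuning knobs.

### Body weight

Per animal the week-1 and week-7 weights are drawn from a bivariate
normal whose margins match the group anchors (control
130.57 ± 12.29 → 349.33 ± 21.76 g; induced 133.75 ± 10.92 →
256.07 ± 51.99 g) with anchor correlation 0.6 (control) / 0.2
(induced — disease severity scrambles the rank order). Intermediate
weeks interpolate:

    w_k = w_1 + f_k (w_7 − w_1) + b_k + e_k,   e_k ~ N(0, τ_k²)

with a monotone group schedule `f`, a group shape offset `b`
(b₁ = b₇ = 0) and small weekly jitter (τ = 3–4 g mid-protocol, 0 at the
anchors). An anchored model was chosen over multiplicative weekly
growth because the control arm's final coefficient of variation
(21.76/349.33 ≈ 0.062) is *smaller* than its initial one
(12.29/130.57 ≈ 0.094), which independent multiplicative increments
cannot produce.

Under this model the probability that an animal weighs less than the
week before is a closed-form normal CDF, so the two dip offsets are
solved exactly so that 81.25 % of induced animals lose weight into
week 3 (the week after STZ) and 93.75 % into the final week. The
week-3 and final-week group means consequently dip, reproducing the
negative mean weight gain in those weeks; control trajectories are
strictly increasing with a loss probability below 10⁻⁷ at every
transition.

### Glucose

Measurements occur at weeks 4 and 6, fasted (12 h) and fed (2 h), per
the reported measurement table. Fasted values and fed control values
are normal at the published means/SDs. Fed induced glycaemia at week 4
is a normal whose parameters are solved (closed form + root find) so
that exactly 56.25 % of its mass lies above the 600 mg/dL ceiling and
its ceiling-censored mean is 568.92 mg/dL. At week 6 three randomly
chosen induced animals are persistent *low responders* (fed glycaemia
~N(210, 25), inside the < 250 mg/dL region the study's boxplot rule
flags as outliers) while the remaining thirteen draw from N(750, 50),
virtually all censored — so the censored readings alone summarise to
600.00 ± 0.00 and the censored fraction rises from week 4 to week 6
(56 % → 81 %). The week-4 censored mean is interpreted as taken over
all sixteen animals (the low responders only manifest at week 6); this
is the only reading of the two published week-4 numbers that is
simultaneously consistent with both.

### Temperature, consumption, welfare events

Forehead temperatures are a shared N(36.0 °C, 0.25) for all animals
and weeks — the study found no group effect, and group means stayed
within 35.9–36.1 °C. Food consumption (g/animal/day) is suppressed in
the induced arm during the fructose weeks (≈10–13 vs 16–19) and
elevated after STZ (≈26–28 vs 20–22, polyphagia); water intake is
elevated throughout and jumps after STZ (≈70–95 vs 24–27 mL/animal/day,
polydipsia). Cage records are generated at 4 animals per cage (the
protocol housed 3–5).

Welfare events are per-parameter, per-week Bernoulli draws for induced
animals only (controls stay at zero, as observed), independent across
weeks — deliberately memoryless, because the study explicitly reports
non-persistent alterations (signs appearing, resolving, reappearing).
Onset weeks follow the reported timeline: dehydration from week 2
(probability 6/16, the reported count), grooming loss and orbital
narrowing from week 3, curved posture from week 5, diarrhoea and
abdominal signs at the end. Probabilities not pinned by a reported
count are documented defaults chosen so the expected per-animal weekly
total stays near or below 1 even in the worst week; the critical total
of 4 is then reached in under 3 % of induced animal-weeks at week 7 and
in no animal-week in roughly three quarters of replicates, mirroring a
study in which no animal ever hit the critical limit while the induced
arm's maximum scores remained clearly above the controls'. All three
observers record identical levels by default; an optional disagreement
probability perturbs individual observers.

### Calibration recovery

`recover_calibration` aggregates ≥ 100 replicates into Monte-Carlo
means of every calibrated summary (anchor weight means, dip loss
fractions, fasted glucose means, censored fractions, temperature,
the week-2 dehydration frequency) and compares them with *analytic*
expectations computed from the configuration — closed forms, not
simulation — so the check is a genuine two-route comparison. The test
suite requires agreement within 3 standard errors at 500 replicates.

## Numerical and I/O conventions

* CSV: comma-separated UTF-8 with mandatory headers, "." decimal, the
  literal `HI` for above-range glucose; weeks 1-based. Writing sorts
  rows deterministically, so write → read → write is byte-identical.
* All simulation randomness flows through one `numpy` Generator; a
  (config, seed) pair reproduces the dataset bit-identically.
* Weights are rounded to 0.01 g, temperatures to 0.1 °C, glucose to
  1 mg/dL — instrument resolutions; the rounding bias is far below the
  Monte-Carlo tolerances used anywhere.
* Problem sizes in the test-suite and the reproduction script: 200
  replicates for the temperature envelope and the weight-loss
  calibration check, 500 for parameter recovery — enough for the 3-SE
  criteria to be sharp while a full run stays in tens of seconds.

## Known limitations

* The simulator is phenomenological: no β-cell/insulin dynamics, no
  mortality (none occurred in the emulated study), no carry-over of
  welfare signs between weeks, no cage-level clustering of welfare
  events, and temperature has no disease effect by construction.
  Passing tests show the *pipeline* is correct and the emulation
  matches the published summary statistics; they cannot validate the
  biology of a new study arm.
* Per-week welfare probabilities beyond the reported counts are
  plausible defaults, not estimates.
* The two-way ANOVA treats animal-weeks as independent observations
  (as the original analysis did); repeated-measures covariance
  modelling is out of scope.
* Serum biochemistry endpoints (albumin, cholesterol, triglycerides)
  are not modelled; kidney relative weights are generated only as
  calibration constants for the relative-organ-weight calculator.
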