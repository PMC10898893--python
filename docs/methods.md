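# Methods

## The scoring model

The package implements the advanced-disease variant of the ASCO value
framework as a deterministic pipeline over a structured trial summary
(`TrialEvidence`): one test regimen against one comparator, scored in six
steps.

**Step 1 — clinical benefit.** The efficacy evidence forms a strict
hierarchy; only the highest available rung is scored and the rung used is
recorded in provenance:

| rung | evidence | score |
|---|---|---|
| 1.A | death hazard ratio | (1 − HR) × 100 |
| 1.B | median overall survival | 100 × (m_test − m_comp) / m_comp |
| 1.C | progression hazard ratio | (1 − HR) × 100 × 0.8 |
| 1.D | median progression-free survival | 100 × Δm/m_comp × 0.8 |
| 1.E | response rate | 100 × (rr_test − rr_comp) × 0.7 |

All four built-in trials report a death HR, so only rung 1.A is exercised by
the shipped fixtures; the lower rungs and their multipliers are configurable
(`ScoringConfig.benefit_multipliers`) and covered by unit tests. A hazard
ratio above 1 produces a negative clinical benefit: harm is reported with a
warning, never clamped, since silently flooring at zero would hide it.

**Step 2 — toxicity.** Each adverse event contributes points by grade band
and frequency: grade 1–2 events score 0.5 below a 10% frequency and 1.0 at or
above it; grade 3–4 events score 1.5 below 5% and 2.0 at or above it (the
thresholds take the "≥" branch exactly at the boundary; frequencies are
stored as proportions to keep 0.10 unambiguous). Per-arm totals T are then
combined as (1 − T_test/T_comp) × 20, negative when the test regimen is more
toxic. Grade-5 events, if supplied, are folded into the grade 3–4 band with a
warning, since the framework defines points for grades 1–4 only. Arms whose
itemization is unavailable carry a `precomputed_total` instead; this is how
the four fixtures store their published totals.

**Step 3 — bonus points.** The tail-of-the-curve bonus compares surviving
proportions at twice the comparator's median: eligible when more than 20%
survive on the comparator and the test arm's proportion is at least 50%
greater. The framework grants "up to 20 points" without a magnitude formula,
so eligibility is computed from the rule while the magnitude comes from the
evidence's `awarded_points` when present (the published nmCRPC scorecards
award 16) and defaults to the full 20 otherwise. Palliation, quality of life
and treatment-free interval each contribute 10 points iff the corresponding
significance flag is true; an absent flag means "not reported" and scores 0.

**Step 4 — net health benefit.** The exact (unrounded) sum of the three
components. The nominal maximum of 180 points is kept as a configurable
constant with a caveat: the component caps implemented here sum to 170
(100 + 20 + 3 × 10), and the pipeline only warns if an NHB exceeds the
configured maximum rather than resolving the discrepancy.

**Steps 5–6 — economics.** Monthly drug cost is price-per-mg × daily dose ×
30 days, rounded to whole Colombian pesos; a treatment month is fixed at 30
days, consistent with the published 120 tablets/month at 4 tablets/day
(calendar-month costing is out of scope). Cost per NHB point is the monthly
cost divided by the NHB, rounded to whole COP and undefined (an error) for
NHB ≤ 0. The model covers drug acquisition only — no administration,
monitoring or out-of-pocket costs. USD conversion uses a configurable rate
defaulting to 3,915.3 COP/USD, back-solved from the published COP/USD pairs
(no rate or date is stated with them); converted values therefore agree with
the published USD figures to within ~0.5%, not exactly.

## Rounding

Component scores (clinical benefit, toxicity) are **truncated toward zero**
at `component_decimals` (default 2) before summation, and the NHB is their
exact sum. Truncation, not half-up rounding, is the convention the published
worked scorecards follow: (1 − 27/22) × 20 = −4.5454… is scored −4.54, which
rounding would turn into −4.55 and break the printed NHB of 33.46
(22 − 4.54 + 16). A half-even pre-round at 9 decimals absorbs binary
floating-point noise so exact decimal ratios (e.g. 44.5/40 → −2.25) are never
truncated past their true value. Whole-COP amounts use ordinary
round-to-nearest.

## The PROSPER toxicity inconsistency

The published PROSPER scorecard prints adverse-event totals 49.5 vs 38, whose
formula value is −6.05, yet scores toxicity as −4.64 and builds the NHB of
48.36 from it. The fixture stores both; `build_scorecard` exposes
`toxicity_source={"reported","computed"}` (default "reported", which
reproduces every published NHB), always records both values and a conflict
flag in provenance, and warns whenever they disagree. Relatedly, the
published abstract rounds that NHB to 48.33; the internally consistent 48.36
is used.

## Uncertainty propagation

An extension beyond the published analysis (which reports hazard-ratio CIs
but scores only point estimates): the HR is drawn from a log-normal with
standard error ln(ci_high/ci_low) / (2 × 1.959964), centred at the geometric
mean of the CI bounds — the unique log-normal whose 2.5/97.5% quantiles equal
the reported interval. For a CI symmetric in logs around the point estimate
this centre is ln(point); printed CIs are rounded, so the two can differ
slightly (PROSPER: geometric mean 0.7368 vs point 0.73). Each draw passes
through the full scorecard with toxicity and bonus held fixed, a documented
limitation — no uncertainty distributions exist for those components, nor for
prices. Because the NHB is an affine, strictly decreasing map of the HR, its
p-quantile equals the scorecard at the HR (1−p)-quantile, up to the
component-rounding granularity; cost per point is reported as NaN on draws
with non-positive NHB.

## Synthetic trials

The generator emulates the evidence structure the pipeline consumes: two arms
of exponential event times (comparator hazard ln 2 / median; test hazard =
true HR × that) with **no censoring**, binomial adverse-event counts at
specified per-arm frequencies, and bonus flags set from the configured truth.
Exponential survival keeps every oracle closed-form: the comparator's
survival at twice its own median is exactly 0.25, the test arm's is
0.25^HR, and tail-of-curve eligibility holds iff HR ≤ ln(0.375)/ln(0.25) ≈
0.7075. The HR is estimated by the exponential rate-ratio MLE (events / total
follow-up per arm) with a log-normal CI using SE = √(1/d_test + 1/d_comp);
a Cox partial-likelihood fit serves as an independent cross-check in the test
suite. Survival and adverse-event draws use separate random streams derived
from the one seed, so changing the adverse-event specification never perturbs
the survival times.

What the generator does **not** emulate — censoring, non-proportional
hazards, dependence between toxicity and survival, and the subjective
adjudication behind the bonus flags — bounds what passing tests show: they
validate the scoring arithmetic and the estimator's consistency under the
ideal model, not robustness to real-world trial features.

Default study conditions for the validation experiments: recovery runs use
grids of true HRs spanning 0.5–1.0 with 4,000–5,000 subjects per arm (large
enough that sampling error in a survival proportion is well under one
percentage point) and 20–100 replicates; the eligibility-threshold experiment
uses a 0.01-spaced grid around 0.7075 with 60 replicates per point and linear
interpolation of the crossing. These sizes are the package's own choice of
"large-trial" conditions for consistency checks.

## Degenerate inputs and tie-breaks

- Empty toxicity profile: total 0 points; a comparator total of 0 makes the
  toxicity ratio (and score) undefined — an error, not a silent 0.
- Degenerate HR CI (low = point = high): zero-variance sampling; all draws
  equal the point.
- Tail evidence whose assessment time differs from twice the comparator
  median by more than 5% is scored but logged as a warning.
- Daily doses that are not whole tablets are costed as prescribed
  (price × mg) while tablet counts are ceiled per day, with a warning.
- The efficacy hierarchy is strict: lower rungs are ignored whenever a higher
  rung is present, even if both are reported.

## Known limitations

Only the advanced-disease framework is implemented (no curative-setting
variant); evidence is entered as structured summaries, not parsed from
registries or publications; cost covers drug acquisition only; the bonus
components carry no uncertainty; and the synthetic generator's exponential,
censoring-free model is an idealization (administrative censoring is a
natural extension).
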