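# Methods

## The measurement problem

Patients on antiretroviral therapy must take medicines continuously for
life, but clinics in resource-limited settings typically have only paper
records: a pharmacy register of what was dispensed and for how many days,
an appointment book, and adherence remarks ("perfect / good / poor") in
the medical chart.  `adhkit` turns those three streams into cumulative
adherence and attendance indicators, estimates how the indicator families
relate to one another, and validates them as predictors of the two
clinical quantities such clinics can actually observe early in therapy:
weight gain and the change in CD4 count.

## Day conventions

All date arithmetic is in whole days.  ART initiation is day 0; the
coverage window for an "as-of" date is half-open, `[0, asof)`, so the
dispensing collected at the as-of visit itself does not contribute to
coverage "to date".  Observation is censored at 18 months (548 days) or
at the data-collection date, whichever is earlier.  Model time uses
30-day month bins.

## The supply-pool coverage model

Each dispensing adds its effective days of supply to a pool; one unit is
consumed per day while the pool is positive; a day is covered iff the
pool is positive on entering that day (counting same-day dispensings).
Consequences of this definition:

* **Carryover.** An early refill stockpiles: supply left from the
  previous dispensing is credited, so coverage never drops merely because
  a patient came early.
* **Multi-component regimens.** The effective supply of a dispensing is
  the *minimum* days of supply across its components — therapy is covered
  only while every drug is available.  This is the conservative choice;
  the alternative (maximum, or per-drug averaging) would count partially
  covered days as covered.
* **Treatment gap.** A gap is a maximal run of consecutive uncovered
  days; the binary flag requires a run *strictly* longer than 30 days.
  Uncovered days after the last dispensing up to the as-of date count, so
  a patient who stops refilling accrues a gap.
* **Exhaustion timeliness (deliberate asymmetry).** The
  "% of visits before medicines finished" measure does *not* carry
  supply over from earlier visits: a visit is timely iff it occurs on or
  before (previous visit's dispensing date + that dispensing's supply).
  The measure is designed for record systems with no scheduled-visit
  data, and its known pessimistic bias — it ignores leftover medicines —
  is part of its definition, so the engine reproduces it rather than
  "fixing" it.

The production implementation builds covered-day intervals with O(events)
pool arithmetic; the test suite holds it exactly equal to a literal
day-by-day pool simulation on randomized dispensing histories.

## Eligibility screen

Criteria are applied in a fixed order with exclusion attributed to the
first failure: age ≥ 18 at initiation; no prior ART (PMTCT prophylaxis
excepted); ≥ 1 visit in each of the first two 91-day quarters (days 1–91
and 92–182); ≥ 1 self-report in those quarters; any dispensing data; and
a baseline CD4 test within 91 days before initiation.  Pill counts are
out of scope throughout (too inconsistently recorded to be usable in the
source setting), so the self-report criterion stands alone.  First-failure
attribution makes the per-criterion exclusion fractions sum exactly to
the overall exclusion fraction.

## Index visit and banding

Cross-sectional summaries are taken at the follow-up visit nearest day
180 (equidistant ties break to the earlier visit).  Coverage percentages
are carried at full precision and banded only for display or modelling:
descriptive bands `<80, 80–<85, 85–<90, 90–<95, 95–<100, 100` and model
bands `<80, 80–<90, 90–<100` with exact-100% as the reference level.
Bands are upper-exclusive except the exact-100 band.

## Correlations

Pearson product-moment coefficients for continuous-continuous pairs;
Kendall rank correlation for any pair involving a binary measure.  The
tie-corrected tau-b is used — with binary data the un-corrected tau-a
cannot reach ±1 and is effectively degenerate, so tau-b is forced in
practice.  Each cell is computed on pairwise-complete observations, so n
varies by cell: self-report pairs exclude two-level-coding facilities,
schedule-based pairs exclude patients with no recorded scheduled dates.
P-values are two-sided asymptotic by default; for n ≤ 12 a small-sample
option uses the exact tau null distribution when there are no ties and a
seeded Monte-Carlo permutation test (20,000 permutations) when there are
— full enumeration of permutations is not attempted.

## Validation models

**Weight.** Weight change from baseline is modelled at every visit in the
first 270 days with generalized estimating equations: identity link,
patient as the cluster, exchangeable working correlation, robust
(sandwich) variance.  Exchangeable is the conventional default for
repeated anthropometry, and the sandwich estimator keeps inference valid
if it is wrong; an independence structure is available for the degenerate
check that GEE with singleton clusters reproduces OLS.  Time enters as
categorical 30-day month bins (a continuous-linear option exists).

**CD4.** CD4 change between the baseline test and one follow-up test in
days 91–270 (nearest day 180, ties earlier) is modelled by OLS with days
to test as a covariate.

Both families adjust for gender, age band, marital status, clinic
location, baseline CD4, WHO stage (1–2 vs 3–4), TB at initiation, any
side effect/opportunistic infection to date, number of distinct regimens
to date, and ever-on-PI; the weight model adds baseline weight.  Each
indicator is entered separately.  The average self-report enters as a
3-level categorical (all perfect; 1 < mean < 2; mean ≥ 2) rather than as
a continuous score.  Missing covariates are handled by complete-case
analysis with counts reported in the results object.

**Adjusted predictions** come in two modes: a typical-patient prediction
at a fixed profile (age 31–40, capital, married, baseline CD4 139.8,
baseline weight 52.8 kg women / 57.2 kg men, 1.6 regimens, no side
effects, never on PI), and a population-averaged prediction that fixes
the indicator level and horizon while the remaining covariates keep their
observed distribution; the latter equals the mean of per-row predictions,
with a delta-method CI from the averaged design row.

## Synthetic cohort generator

The generator emulates the event-log structure of the study setting; it
defines the conditions under which everything here is tested.

* **Demographics** are drawn independently from the observed marginals
  (62.5% female; age bands 29.3/43.4/27.3%; education 15.5/46.7/37.8%;
  44.1% married; 63.5% government facilities; location 49.8/26.4/23.8%;
  WHO stages 8.9/25.4/54.4/11.3%; baseline CD4 bands ≈37/40/21/2%;
  baseline weight N(57.2, 9.2²) kg men, N(52.9, 9.7²) kg women; two of
  the printed vectors were renormalized by 0.1 percentage points to sum
  to 1).  A quarter of facilities use the two-level self-report coding.
* **Behavior.** One latent propensity z ~ N(0, 1) per patient shifts
  three base probabilities on the log-odds scale: on-time refill (0.95),
  missed visit (0.015), and long interruption (0.010).  Visits are
  scheduled 30 days after the previous attendance; each attended visit
  dispenses 30 days of supply.  Late arrivals draw a lateness from a
  mixture (60% 1–3 d, 25% 4–7 d, 10% 8–14 d, 5% 15–30 d).  An
  interruption stops attendance until `31 + Geom(1/15)` (capped at 85)
  days after the current supply runs out, triggered at a day drawn
  uniformly in 30–150 — most real treatment interruptions happen early.
  The behavioral base rates were calibrated so the emergent index-visit
  distribution sits near the observed anchors (~63% full coverage, ~3%
  long gaps, ~75% all-perfect self-reports).
* **Self-reports** are recorded at 90% of visits.  A true lapse (any
  uncovered day since the last visit, or > 3 days late) is still reported
  as perfect with probability 0.8 — the optimism that makes recorded
  self-reports overestimate adherence; otherwise it is coded good (85%)
  or poor (15%).  Without a lapse the code is perfect 96% of the time.
* **Outcomes.** Weight follows a concave piecewise-linear trajectory
  (monthly gains 1.4, 1.0, 0.6, 0.4, 0.3, 0.2, 0.15, 0.10, 0.05 kg:
  3.9 kg cumulative at month 6, plateau ≈4.2 kg by month 9), plus
  coverage-band penalties (−2.24 kg below 80%; −0.51 / −0.52 kg in the
  mid bands) and a −3.26 kg penalty once a >30-day gap has occurred, all
  evaluated on the patient's *true* running coverage at each visit.
  Residuals are an exchangeable patient intercept + visit noise (3.0 kg
  each, within-patient correlation 0.5 — a free choice, as no
  within-patient correlation is observable from published summaries).
  One follow-up CD4 test is drawn uniformly in days 91–270; its gain is
  148.8 cells/mm³ under full coverage with band penalties −97.3 / −28.8
  / −22.1 and noise SD 120.
* **Determinism.** A single `numpy` generator seeded from (config, seed)
  drives everything; identical inputs give byte-identical written
  cohorts.

What the generator does **not** emulate: mortality and loss to follow-up,
facility-level clustering, covariate effects on outcomes (demographics
are independent of adherence and outcomes), viral load, drug resistance,
seasonal or stock-out effects, and measurement error in dates.  Passing
tests therefore demonstrate that the estimators recover known effects
under clean longitudinal structure — not that they are robust to the
messiness of real registries.

## Simulation experiment sizes

Effect-size recovery and confidence-interval calibration use 200
replicate cohorts of n = 488 with a 9-month observation window (the
analysis window for both outcomes) and an elevated interruption base rate
(0.025) so that each replicate contains enough gap patients for stable
per-replicate estimates; only the effect under study is switched on, so
the recovered coefficient estimates the configured truth rather than a
mixture of the co-occurring gap and low-coverage penalties.  Sign
structure and marginal fidelity use one n = 10,000 cohort.  Oracle
equivalence uses 1,000 random dispensing histories; tau-b equivalence
uses 500 random vectors of n ≤ 50.

## Degenerate inputs and numerical choices

Zero-variance or all-tied vectors yield an "unestimable" correlation cell
with a reason rather than NaN.  An indicator constant in the estimation
frame, a non-convergent GEE, or a profile missing a covariate raises an
error naming the problem.  Dispensings before initiation are hard errors;
dispensings at or after the as-of date are ignored and counted.
Snapshots before the first visit or beyond the censoring horizon are
refused.  Percentages are rounded only at report time (1 decimal;
coefficients 3 decimals).

## Known limitations

Whether the source analyses applied stockpiling exactly as modelled, used
tau-a or tau-b, or coded GEE time continuously is not knowable from
published text; each is implemented as the defensible default documented
above and, where reasonable, left configurable.  Exclusion fractions from
the screen are reported over the patients actually screened; no claim is
made about reproducing any particular screening denominator.  Dropout
prediction is out of scope by construction: the eligibility criteria
require months of retention, so early failures are invisible here.
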