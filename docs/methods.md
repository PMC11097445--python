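# Methods

`mm_lookback` implements a population-level multimorbidity analysis over
administrative health claims: chronic conditions are ascertained from
retrospective hospital and physician claims under lookback periods (LPs) of
1–20 years, multimorbidity prevalence is estimated under count-based
criteria, and the added value of the multimorbidity indicator for predicting
six one-year health outcomes is measured across the full factorial of
design choices.  Because linked claims registries are confidential, the
package ships a synthetic-claims generator that reproduces the *structure*
of such data; nothing in it is calibrated to any real population.

## Case definition and the minimal-lookback representation

A condition is considered present within a retrospective window when either

* at least one hospital discharge diagnosis carries one of the condition's
  ICD codes, in any position (admission, primary or secondary); or
* at least `min_physician_claims` (default 2) physician-claim diagnoses for
  the condition occur on **distinct service days** whose first-to-last span
  is between `min_spacing_days` (default 30) and `max_pair_span_days`
  (default 730) days.

Interpretation choices the rule text leaves open, fixed here:

* "Within two years" is a pair span ≤ 730 days; "at least 30 days apart" is
  a span ≥ 30 days, both bounds inclusive.
* Both claims of a qualifying pair must fall inside the lookback window;
  pairs straddling the window start never qualify.
* The hospital qualifying date is the admission date.
* Inpatient, outpatient and emergency-department physician claims all count
  toward the physician rule.
* Two same-day claims for a condition count once (distinct service days).
* When `min_physician_claims` = m > 2, the rule requires m claim-days whose
  first and last satisfy the same span constraints (for m = 2 this is
  exactly the classic pair rule).

Windows are half-open `[index − L years, index)` with calendar-year
arithmetic (a Feb 29 start maps to Feb 28).  Windows of increasing length
are nested, and both a qualifying hospital claim and a qualifying claim set
remain inside every longer window, so ascertainment is **monotone** in L.
The per-person × condition result is therefore stored as a single *minimal
lookback*: the smallest L at which the condition is ascertained.  This
compresses a 20-slice boolean cube into one integer per ascertained pair and
is validated against exhaustive per-window evaluation by brute-force oracle
tests.  A per-condition cap of C years (used for remitting mental disorders
and disease-specific definitions) truncates every window longer than C to C,
which preserves monotonicity and only ever removes ascertainments.

ICD matching is prefix-based on normalised codes (upper-cased, dots
stripped); exact-code lists are representable as full-length prefixes.  The
coding era is derived from the claim date — hospital abstracts switch from
ICD-9 to ICD-10 at 2006-04-01, physician claims at 2019-01-01 — and both
switch dates are carried on the cohort specification so synthetic scenarios
can move them.

## Cohort, outcomes and eligibility

The cohort comprises persons aged ≥ 66 completed years and alive at the
index date (default 2019-04-01), followed one year (to 2020-03-31).  Six
binary outcomes are built from follow-up claims:

| outcome | definition |
|---|---|
| death | death date within the follow-up year |
| hospitalisation | ≥ 1 admission |
| polypharmacy | ≥ 10 distinct medications (common-denomination identifier) |
| frequent ED | ≥ 3 collapsed ED visits |
| frequent GP | ≥ 7 GP visit-days |
| frequent specialist | ≥ 10 specialist visit-days |

An ED *visit* collapses all ED-flagged claims occurring on up to two
consecutive calendar days, grouped greedily from the earliest unassigned
day; greedy-from-earliest is deterministic and matches common episode
construction (a brute-force minimal-interval oracle confirms equivalence).
A GP/specialist visit is one claim-day per provider type; ED-flagged claims
are excluded from GP/specialist counts so an ED encounter is not double
counted as an office visit.  Visit thresholds are fixed constants, not
re-estimated percentiles.  Non-mortality outcomes are analysed only in
persons alive through follow-up end with drug-plan coverage over **every**
day of the follow-up year (a one-day gap breaks eligibility).

## Prevalence

Multimorbidity under criterion MMk+ is an unweighted condition count ≥ k
(k = 2, 3, 4).  Prevalence curves over LP 1–20 use the full cohort as
denominator (not the coverage-restricted subcohort) and report the
year-over-year relative change `(prev_L − prev_{L−1}) / prev_{L−1}`, the
natural discrete growth rate; it is undefined at L = 1 and when the previous
prevalence is zero.  Curve monotonicity and criterion nesting
(MM4+ ⊆ MM3+ ⊆ MM2+) are asserted, not assumed.

## Prediction models and metrics

For each (outcome, list, criterion, LP) a logistic model is fit with a
single binary multimorbidity indicator plus baseline covariates: age band
(six categories: 66–69 … 90+), sex, and material and social deprivation
quintiles with an explicit `missing` category.  Deprivation enters
categorically (the ordinal alternative was rejected to avoid imposing
linearity).  The indicator — rather than the raw count — follows the framing
of MMk+ as alternative *definitions* under comparison.  Within age strata
the bands interior to the stratum are used; a rank-revealing QR drops
aliased dummies (e.g. the joint missing-deprivation category, which appears
in both quintile factors and would otherwise make the design singular).
With 3 lists × 3 criteria × 20 LPs × 6 outcomes the sweep fits 1080
multimorbidity models plus 6 baselines per stratum.

Performance is **apparent** (in-sample); no split-sample or bootstrap
optimism correction is applied, matching the design this package
benchmarks, where stratified checks replace resampling.  Metrics:

* **c-statistic** — concordance probability over event/non-event pairs with
  ties counted ½ (equals the area under the ROC curve), computed via
  midranks in O(n log n) and validated against an O(n²) pairwise oracle and
  an independent library implementation.  The 95% CI uses the DeLong
  structural-components variance estimator.  A difference > 0.010 between
  two models' c-statistics is treated as meaningful.
* **Scaled Brier score** — `1 − BS/BS_ref` with `BS_ref` from the constant
  event-rate predictor.
* **Calibration** — slope is the coefficient of logit(p) in a logistic
  refit of the outcome; intercept is fit with logit(p) as a fixed offset
  (calibration-in-the-large).  Predictions are clamped to (1e−12, 1−1e−12)
  before the logit.  For in-sample maximum-likelihood fits slope 1 /
  intercept 0 hold identically, a consistency check the sweep reports.

Maximal performance per (list, criterion, outcome) reports the maximum
c-statistic over the LP grid, the LP at which it is first reached (ties
break toward the shortest LP) and the band of LPs within 0.001 of the
maximum.  Degenerate strata (one outcome class) and non-convergent fits
yield flagged rows rather than aborting the sweep; separation is flagged
when Newton fails or fitted probabilities hit the numerical boundary, with
a BFGS fallback.

## Synthetic-claims generator

The generator emulates the features the analysis relies on:

* **Persons** — age bands with weights (0.258, 0.279, 0.196, 0.129, 0.086,
  0.052) over 66–69 … 90+, 55.2% female, deprivation quintiles uniform with
  an 11.8% jointly-missing rate — the mix of a typical over-65 registry
  cohort.
* **Onsets** — per condition, an age-dependent exponential waiting time
  with hazard `λ₀ exp(0.04 · (age − 65))`; conditions are permanent except
  groups flagged remitting (mood/anxiety/psychotic/substance disorders),
  which remit with probability 0.3 after an exponential duration (mean 6
  years).  Default baseline hazards are log-spaced over 3·10⁻⁴–1.2·10⁻²
  per year, giving lifetime prevalences of roughly 1–30% and a mean true
  count near five conditions — enough dispersion for MM2+–MM4+ to separate.
* **Claim emission** — per active condition-year, one Bernoulli hospital
  stay (probability 0.02–0.12 by condition) and Poisson physician claims
  (mean 0.2–0.8), carrying the condition's era-appropriate code with a
  random digit suffix; plus Poisson(0.3)/year non-chronic background claims.
  Rates are spread across conditions by fixed stride permutations so they
  decorrelate from list order.
* **Outcomes** — drawn from logit-linear models on the true condition
  count, age band, sex and deprivation, with intercepts chosen so the
  default scenario lands at plausible rates (mortality a few percent,
  polypharmacy in the tens of percent).  Follow-up utilisation (stays,
  ED/GP/specialist visit-days, pharmacy claims) is then generated
  *conditional on* the drawn outcome indicators, truncated at death; it is
  not an independent utilisation process.  An optional threshold term
  `β_mm · 1{count ≥ k}` supports parameter-recovery experiments.
* **Coverage** — one interval spanning the study period, with a 10% chance
  of a 30–120-day gap inside the follow-up year (matching the fraction of
  older adults outside the public plan).

A fixed seed yields byte-identical output.  The truth table (latent onsets,
true outcome probabilities and drawn indicators) is emitted alongside the
bundle so recovery tests need no re-simulation.

**What passing tests do and do not show.**  The generator has no coding
errors, no provider billing behaviour, no migration in or out of coverage,
no correlation between conditions beyond shared age dependence, and
follow-up utilisation is outcome-driven rather than disease-driven.  Tests
against it therefore validate the *algorithms* — window logic, case rules,
counting, model fitting, metric formulas — not the epidemiology of any real
population; absolute prevalences and c-statistics from the demo scenario
are illustrative only.  Analytic anchors make the validation sharp where
possible: under hospital-only emission with per-year probability h and
always-present conditions, ascertainment prevalence at lookback L must equal
`1 − (1−h)^L`, and the pipeline reproduces this within Monte-Carlo error at
100,000 person-conditions.

## Disease lists

Three demo lists ship with the package — an all-inclusive 60-condition
catalogue (L60), a 20-condition high-burden core (L20, osteoporosis
included) and a 31-condition combined Charlson/Elixhauser-style catalogue
(L31) — as **synthetic stand-ins**: list sizes and structure are faithful,
but the code prefixes are illustrative, not validated code sets.  Real
analyses supply their own YAML in the same schema.  Sensitivity profiles:
a 5-year lookback cap for remitting mental disorders (L60/L31),
per-condition disease-specific rules (L20 only; the shipped defaults
replicate the generic rule with tighter caps for depression, anxiety and
asthma), and a hypertension variant appending a 21st condition to L20.

## Numerical and scale choices

Demo problem sizes were chosen to keep a laptop run comfortable while
leaving Monte-Carlo error well below the tolerances tested: 5,000 persons
for the factorial sweep and prevalence curves (~30 s end to end), 100,000
person-conditions for the closed-form check (binomial SE ≈ 0.001), and
50,000 persons for calibration and coefficient recovery (3-SE acceptance
bands).  Stochastic tests fix their seeds.  Known limitations: in-sample
performance only; no weighted comorbidity indices; no incident/prevalent
disease dating; deprivation quintiles are taken as given covariates, never
derived from census data.
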