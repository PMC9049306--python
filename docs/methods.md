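# Methods

`scdsim` is an individual-based state-transition model of sickle cell
disease (SCD) built for cost-effectiveness analysis of curative therapies
(gene therapy, hematopoietic stem cell transplant) against Common Care
(no disease-modifying treatment, hydroxyurea, or transfusion, without
transplant).  This note records the model, its assumptions, and the design
choices made where the design was genuinely open.

## Disease representation

A simulated person occupies a *combination* of health states across four
parallel dimensions rather than one mutually exclusive Markov state:

1. **chronic pain** — a single on/off state evaluated every cycle in its
   own dimension, reflecting its near-universal presence in SCD and its
   interaction with everything else;
2. **acute events** — 13 instantaneous within-cycle occurrences (e.g.,
   vaso-occlusive pain episodes, stroke, acute chest syndrome) that leave
   only history counts behind;
3. **chronic disorders** — absorbing conditions (e.g., chronic renal
   disease, pulmonary hypertension and cardiovascular disease) present in
   every cycle after onset;
4. **treatment complications** — per-therapy sets: hydroxyurea
   (leukopenia, thrombocytopenia, oligospermia/azospermia), transfusion
   (iron overload, transfusion reaction, infection), transplant and gene
   therapy (graft failure, bronchiolitis obliterans, osteoporosis, iron
   overload, depression, PRES, PTLD, secondary malignancy, with
   graft-versus-host disease only for allogeneic transplant).

Seven of the 13 chronic-type disease conditions (chronic pain, fatigue,
asthma, leg ulcers, hepatobiliary/liver disease, sleep-disordered
breathing, depression/psychosis) are *subacute*: capable of remission.  On
the claims side a subacute disorder counts as present in year *y* if a
qualifying claim occurs in {y, y−1, y−2}.  The current year is included in
that window deliberately — otherwise a newly diagnosed disorder would be
absent in its own diagnosis year.  The simulator mirrors the same rule: a
subacute "occurrence" draw refreshes a last-active year, and the disorder
stays present for two further cycles.  Using identical annual-flag
semantics on both sides keeps claims-derived and simulated lifetime
prevalences commensurable, which calibration requires.

Cycles are annual; more precise event timing is immaterial over a lifetime
horizon.  No half-cycle correction is applied: the death year counts as a
full lived year for utilities and costs.  This is a documented limitation
knob, not a configurable option.

### Within-cycle order

The cycle order is (1) age advance and acute-slate clearing, (2) treatment
use, (3) chronic/subacute incidence, (4) acute events, (5) complications,
(6) utilization, (7) mortality.  The order is a design choice; what it
must honor are the covariate timing contracts of the prediction indices
(below), which it does.  One consequence: treatment-use draws see the
*standing* (entering-year) disorder status, while the claims-side fit sees
current-year flags that may include same-year onsets.  We accept this
small timing mismatch as the price of a causal within-cycle order.

## Prediction indices

Four families of penalized regressions drive the dynamics, each with a
fixed covariate schema shared bit-for-bit between design construction and
the simulator (module `scdsim.features`):

| family | outcome | covariate timing |
|---|---|---|
| incidence | each of the 26 conditions | previous-year status, history, treatments, complications |
| treatment_use | hydroxyurea, acute/chronic transfusion | current persistent status, history, previous-year treatments/complications |
| complication | each complication attribute | current status and treatments, history, previous-year complications |
| utilization | inpatient admissions, ED visits, outpatient visits | all current-year blocks |

History enters as per-attribute counts of prior flagged years (equal to
duration since onset for absorbing disorders), capped at 8 — the scale of
a claims study window.  The cap matters: fits only ever see counts of 0–8,
and without it the simulator would extrapolate those coefficients to
lifetime-accumulated counts of 25+, saturating probabilities far outside
the support of the data.  The same cap is applied on both the fitting and
simulation sides.  Demographics are sex, 5-year age-band indicators
(0–4 … 95–99), and birth-decade indicators (1920–2010).  Five-year banding
and decade cohorts are our choices; the requirement is only that age and
cohort enter as indicators.

Binary outcomes use elastic-net logistic regression (saga solver, pinned
random state); utilization counts use L2-penalized Poisson regression with
a log link, a pragmatic choice since no count family is prescribed.
Chronic outcomes exclude person-years where the condition is already
present (incidence is onset).  The sample is split 50/25/25 at the
*beneficiary* level (never person-years, to prevent leakage): training,
a first test set used for beneficiary-level bootstrap refits that supply
parameter uncertainty, and a second test set reserved for decision-model
validation.  Penalty strength can be chosen by grouped 5-fold
cross-validation on the training part; the pipeline default uses a fixed
strength of 1.0 (sklearn ``C = 1``) — on demo-scale synthetic panels a
weaker penalty leaves implausibly large coefficients on rare outcomes,
which destabilizes the simulated dynamics, while a grid search adds
runtime without changing behaviour; the CV path is exercised in the test
suite.  Outcomes that are degenerate
in a small synthetic panel (zero events) fall back to an intercept-only
index at a Laplace-smoothed rate; calibration then sets their level.

## Mortality

The claims analyses that would parameterize mortality are out of reach, so
the model uses a transparent parametric form: background annual death
probability `q(age) = a_sex · exp(b · age)` (defaults `a_female = 2.4e-4`,
`a_male = 3.0e-4`, `b = 0.08`), converted to a log-hazard, multiplied by
per-attribute hazard ratios for active conditions (e.g., multi-organ
failure 2.5, chronic renal disease 1.6, stroke 1.5), and converted back,
clipped to [0, 1].  Defaults were chosen once to give the elevated,
comorbidity-graded mortality of an SCD claims population (median death in
mid-to-late adulthood); they are fully configurable.

## Strategies and treatment effects

Curative therapy is offered once, at model entry, to individuals with
severe disease — by default a lifetime history of ≥3 severity-marked acute
events (vaso-occlusive episodes, stroke, acute chest syndrome, multi-organ
failure) or any stroke.  The severity marker set is a declared assumption:
the source material defers "severe SCD" to adverse-event history without
enumerating it.  A responder draw (`p_symptom_free`, default 0.85 for gene
therapy, 0.90 for transplant) decides whether the strategy's risk ratios
apply: responders suppress acute events and chronic pain entirely (risk
ratio 0) and halve chronic-disorder incidence; non-responders keep common-
care dynamics.  Both face attempted-therapy complications with first-year
and subsequent annual probabilities.  Responders stop common-care
treatment use.  A durability scenario wanes the suppression toward no
effect with a configurable half-life.  One-time prices default to
$1.8M (gene therapy, anchored to the approved beta-thalassemia gene
therapy) and $250k (transplant); both are scenario parameters, not
estimates.

Because entry states are otherwise disease-free, the population spec seeds
a prior vaso-occlusive-event count (Poisson with rate 0.15/year of age) so
that the severity gate has a meaningful population to select from.

## Synthetic claims world

Real Medicaid/Medicare/MarketScan data cannot ship with a package, so the
generator emulates their *structure*: month-granular enrollment spans with
optional gaps, dated claims with positioned ICD-9/ICD-10 diagnosis codes
(the edition switches at October 2015), procedure flags for hydroxyurea,
transfusion and transplant, deaths, and non-case beneficiaries (pure-noise
coders, trait-only coders, single-claim near-misses) so case
identification has true negatives.  Scenario demographics reproduce the
published cohorts: Medicaid age at entry mean 16.9 (SD 13.9), 53.4%
female; Medicare 62.3 (16.2), 60.2%; dual-eligible 33.3 (19.5), 58.1%.
Age at entry is gamma-distributed with those moments — a truncated normal
would inflate the Medicaid mean by about three years.  Per-attribute
annual claim probabilities default to values consistent with the published
lifetime prevalences over a nominal 25-year claims history.

What the generator does **not** emulate: CMS file layouts, race/ethnicity,
billing amounts, and — most importantly — any person-level correlation
structure between attributes beyond shared age dependence (only
cohort-level moments are published).  Tests passing against this world
demonstrate that the *machinery* is correct, not that real-claims
parameter estimates would be reproduced.

## Calibration

Claims under-capture pain (episodes reach the healthcare system in a
minority of cases), so the model supports external calibration: a
per-attribute additive shift on the incidence-index intercept (log-odds
scale) is solved so that simulated lifetime prevalence under Common Care
matches published targets (packaged as `prevalence_targets.csv`, by payer
column, default tolerance 2 percentage points).  Because the
intercept→prevalence map is monotone and nearly separable across
attributes, each shift is updated with a secant step on the logit scale
whose slope is learned from the previous iterate (first step damped, steps
capped at ±3), and all attributes share each simulation run, which also
lets the iteration absorb cross-attribute feedback through the indices.
Two details make the root-search reliable.  First, calibration runs use
common random numbers: every iteration simulates with the same seed, and
each simulated person draws a *fixed* number of state-transition randoms
per cycle (utilization, whose Poisson draws consume a data-dependent
number of randoms and which feeds nothing back into the dynamics, has its
own per-person substream).  A small shift change therefore flips only
marginal Bernoulli decisions and the shift→prevalence map is smooth enough
for secant steps.  Second, lifetime prevalence responds super-linearly to
the intercept (annual exposure compounds), so a naive logit-gap update
overshoots and oscillates inside the tolerance band; the learned slope
removes that.  Iteration stops when every target is within tolerance and
the remaining proposed steps are negligible.  Zero targets are
structurally unreachable and are flagged rather than fatal.  Default
calibration cohort: 3,000 lifetimes per iteration (6,000 in the acceptance
workflow), at most 12 iterations; the calibrated model is verified on an
independent seed with 10,000 lifetimes.

## Economics

Utilities: base 0.92 declining 0.001/year after age 18, minus additive
decrements per active condition (chronic pain 0.10, stroke-year 0.12,
multi-organ failure 0.15, …), clamped to [0, 1].  Addition-with-clamp was
chosen over multiplicative combination for transparency; optional pairwise
interaction terms are exposed for the cases where additivity double-counts.
All decrements are configuration, not estimates.

Costs (2019 US$, all configurable): unit costs $15,000/admission,
$1,500/ED visit, $300/outpatient visit; annual treatment costs $1,200
hydroxyurea, $3,000 acute and $40,000 chronic transfusion; future
unrelated medical costs $3,000 + $80·age per year; end-of-life cost
$30,000 in the death year.  The societal perspective adds time-use cost,
modelled linearly as `(1 − utility) × 1,000 hours × $40/hour` — a
transparent stand-in for the published association between time use and
health-related quality of life — and unpaid caregiver time ($12,000/year
for children, $8,000/year for adults with utility below 0.5).  Caregiver
*utilities* are excluded (none have been reported).  Costs and QALYs are
discounted at 3%/year, the U.S. reference-case convention.

ICERs are computed on the non-dominated frontier with standard and
extended dominance; equal-QALY comparisons report the incremental cost
with the ICER flagged undefined.  The PSA samples one bootstrap
coefficient replicate per index (when available) plus multiplicative
lognormal factors on utility decrements and unit costs, reruns a
reduced-size cohort per strategy with common random numbers, and reports
the (Δcost, ΔQALY) cloud and the acceptability curve (fraction of draws
with positive net benefit across a willingness-to-pay grid).

## Numerical and reproducibility choices

* One master seed; every stage, and every simulated individual, draws from
  a named substream (CRC-keyed `SeedSequence`), so growing a cohort leaves
  earlier individuals unchanged and pipeline reruns are bit-identical.
* Degenerate inputs: empty claims tables round-trip; degenerate outcomes
  raise (fits) or fall back to intercept-only (pipeline); probabilities
  that leave [0, 1] after a risk ratio raise naming the attribute.
* Ties: the longest enrollment span breaks to the earliest; censoring-year
  ties resolve death > pre-transplant > window end > disenrollment.
* ICD matching is prefix-based on normalized codes (dots stripped,
  case-insensitive), exclusions applied after inclusions, so stem codes
  cover their children while trait codes stay excluded.
* The shipped ICD code lists for the 26 conditions are illustrative
  placeholders (clearly marked in the registry file) and fully
  overridable; only the SCD case-definition codes are substantive.
* Problem sizes: examples and the demo configuration use 1,500–2,500
  beneficiaries and 2,000 simulated lifetimes; calibration uses 3,000
  lifetimes per iteration and verification 10,000 — sizes chosen so a full
  workflow completes in minutes on one CPU while keeping Monte-Carlo error
  well inside the 2-point calibration tolerance.

## Known limitations

* Transition structure is fit to a synthetic claims world; coefficients
  have no clinical validity.  The package's claim is that the machinery —
  cohort derivation, index fitting, calibration, simulation, CEA — is
  correct and reproducible, ready to be pointed at real claims extracts.
* Mortality, utilities, and costs are parametric placeholders with
  documented defaults rather than estimated quantities.
* Entry states carry only a seeded vaso-occlusive history; prevalent
  chronic conditions at entry are not modelled.
* Acute events are Bernoulli per attribute per year (no within-year
  multiplicity); utilization is conditionally independent across
  categories given covariates.
* No donor availability, no waning-immunity biology, no equity weighting.
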