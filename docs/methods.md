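# Methods

## Adherence measures

**Persistence.** Each patient's treatment episode starts at the index date
(first qualifying dispensation) and is followed for 365 days. Scanning
consecutive dispensing events, the patient is non-persistent at the first
event whose successor arrives later than `gap_multiplier × supply_days`
(default 2×) after the event, or whose successor never arrives when that
much allowance fits before the end of follow-up. Days spent in hospital are
deducted from the gap before the comparison, on the assumption that the
hospital supplies treatment. The time to discontinuation is the day offset
of the last dispensing plus its days of supply. Death before that point
censors the patient at death; otherwise the patient is persistent and
censored administratively at day 365.

Conventions, all configurable:

* 1-month packages supply 30 days, 3-month packages 90 days. Fixed integers
  keep the whole computation exact on a day grid; other package sizes are
  rejected.
* The allowance window is anchored at the dispensing date (`anchor=
  "dispensation"`), the stricter of the two readings of "a period greater
  than 2 times the duration of the previous supply"; `anchor="exhaustion"`
  starts it when supply runs out.
* When package sizes alternate, the allowance uses the *previous* event's
  supply.
* All day intervals are half-open `[start, end)`; hospitalization intervals
  are merged before any overlap computation so overlapping stays are not
  double-counted.
* Month-denominated windows convert to days as `months × 30.4375`, rounded
  down (washout 24 months = 730 days; CMA eligibility 6 months = 183 days).
* Summary quantiles of time to discontinuation enter persistent (censored)
  patients at 365 days. This is the convention under which an upper quartile
  can sit at the follow-up cap, as in the source study's tables; it is a
  descriptive display choice, not a survival estimator.
* A patient whose last dispensation falls too late for the allowance to fit
  before day 365 (e.g. a 90-day package dispensed after day 185) cannot be
  declared non-persistent and is censored as persistent. This is inherent
  right-censoring of the rule, not an implementation artifact.

**Implementation (CMA7).** Over the persistence window `[0, min(time to
discontinuation, death, 365))`, a running supply ledger adds each event's
days of supply to a balance; one balance unit covers each non-hospitalized
day; unconsumed supply carries over at the next event, uncapped (a cap
would be an uncited deviation from the CMA7 definition). Hospitalized days
are covered without consuming supply, extending the remaining supply
accordingly. `CMA7 = covered_days / window_days ∈ [0, 1]`. CMA7 is computed
only for patients under treatment at least 183 days; a death between month
6 and the end of the window truncates the window at death rather than
excluding the patient. Good implementation is `CMA7 ≥ 0.90`, closed at the
top.

The event-driven ledger is validated against an independent brute-force
day-grid simulation (`cma7_reference_day_grid`) — exact integer agreement
on covered days for arbitrary episodes, enforced by property tests and the
acceptance suite (1,000 random episodes).

## Cohort selection

New users are patients whose first in-window study-drug dispensation has no
study-drug dispensation in the preceding 730 days (bisphosphonate–vitamin-D
combinations count as study drugs for the washout but cannot qualify as the
index product). The index dispensation fixes group (brand/generic),
molecule, administration frequency and prescriber specialty. Exclusions
over a 24-month lookback: ≥ 3 corticosteroid reimbursements, or any
hospitalization whose ICD-10 code prefix-matches the configured exclusion
list (dot-stripped matching: `"S720"` matches `"S72.00"`, since claims
extracts vary in dot usage). Patients who switch brand↔generic within the
same molecule, or change molecule, during follow-up are removed, with
counts kept per group and kind; a patient with no post-index dispensation is
retained (non-persistence is not switching). Every filter appends to an
attrition record whose counts are enforced to be non-increasing. Same-day
multiple dispensations at index are resolved by a deterministic sort
(patient, date, molecule, brand flag), taking the first row. The source
database's "present at least 3 years" enrollment requirement maps, in the
synthetic setting, to the washout-length observability the generator
guarantees by construction.

## Propensity and weights

The probability of initiating brand is fit by logistic regression (binomial
GLM) with: sex, age (continuous), CMU status, polypharmacy, Charlson class
(0 / 1–2 / ≥3), fracture history, year of initiation (categorical, 7
levels), administration frequency, prescriber specialty, and a
year × frequency interaction. Rows with missing/unknown prescriber
specialty are dropped and counted. Stabilized weights use the *empirical*
brand share `P(T)` of the fitted rows as the stabilizing marginal:
`sw = P(T)/e` for brand, `(1−P(T))/(1−e)` for generic, so mean(sw) ≈ 1 and
the weighted group sizes keep the original shares. No weight truncation is
applied by default.

Complete separation (every fitted probability at its own outcome) raises an
estimation error naming the most extreme term. Sparse year × frequency
cells can produce quasi-separation (boundary fitted probabilities for a few
rows); these are logged and clipped to (1e-10, 1−1e-10) rather than treated
as failure, which is the standard practical handling.

Balance is reported as standardized differences, continuous
`d = (m₁−m₂)/√((s₁²+s₂²)/2)` and binary `d = (p₁−p₂)/√((p₁(1−p₁)+p₂(1−p₂))/2)`,
pre- and post-weighting (weighted moments), one row per level for
categorical covariates, with the conventional |d| ≤ 0.10 flag. Age is
reported both continuous and in 10-year classes, since either can be the
diagnostic of record. ALD status is summarized in the baseline table but is
not a propensity-model covariate, so it does not appear in the balance
report. Zero pooled variance with unequal means reports an infinite d and
is flagged.

## Effect models

**Weighted Fine–Gray.** The discontinuation effect is the subdistribution
hazard ratio with death competing. Patients with a prior death remain in
later risk sets with time-decaying weight `G(t⁻)/G(T_i⁻)`, where `G` is the
unweighted Kaplan–Meier estimate of the censoring distribution (the
original formulation's default). External IPTW weights multiply each
subject's risk-set contribution and are treated as fixed. Ties use the
Breslow approximation (ties are frequent with day-granular data). The
variance is a Lin–Wei-type robust sandwich built from per-subject score
residuals; no Monte-Carlo bootstrap is used. The single-covariate (group)
partial likelihood is maximized by Newton steps with step-halving,
converging on `|Δβ| < 1e-10` or a score below 1e-8 of the weight mass.

Risk-set sums are decomposed into a suffix sum over subjects still at risk
plus `G(τ⁻) ×` a prefix sum over prior deaths, giving O(n log n) evaluation
— a single fit at n = 100,000 takes seconds. With zero competing events the
estimator reduces *exactly* to weighted Breslow Cox; the test suite checks
coefficient agreement with an independent Cox implementation to 1e-6, and
the implementation was additionally cross-validated against the reference R
implementation of the competing-risks regression (coefficients and robust
SEs agree to its convergence tolerance) during development.

**Weighted log-binomial.** The good-implementation risk ratio is
`exp(β_group)` from a binomial GLM with log link, group as sole covariate,
IPTW `var_weights`, started at the pooled log-rate, with an HC0 sandwich
CI. A constant outcome (all good / all poor) raises a degenerate-outcome
error; non-convergence (fitted probabilities pushed above 1) is reported as
an estimation error.

## Synthetic claims generator

The generator emulates the structure the analysis consumes, not any real
person-level data: per-patient covariates drawn from study-scale marginals
(≈89% female, mean age 70.5 ± 10.5, 7 initiation years with declining
counts, daily/weekly/monthly frequencies, prescriber specialties with a
small "unknown" share), treatment assigned by a logistic model on those
covariates (so confounding is real), and an intercept calibrated so the
finite-sample mean assignment probability equals `brand_share` exactly.
Trajectories use integer day offsets from the index date; ISO dates are
emitted by adding offsets, avoiding month-length ambiguity.

Key defaults (all `SimulationParams` fields):

* `brand_share = 0.56` — analysis-group scale of the emulated study.
* `discontinuation_hazard_brand/generic = 0.165 / 0.14` per refill cycle
  (geometric, matching the cycle granularity the persistence rule
  observes). These give ≈ 27% / 33% 12-month persistence and a
  subdistribution HR ≈ 1.16 — the study's 12-month persistence scale with
  an effect detectable at the calibration-study scale below. A constant
  per-cycle hazard cannot also reproduce the study's strongly front-loaded
  discontinuation (median ≈ 103 days); matching the 12-month scale was
  chosen.
* `package_mix = 0.25` — probability of a 3-month (90-day) package.
* `refill_delay_distribution = U{−3..14}` days — late-skewed jitter that
  exercises the 2×-supply rule without guaranteeing discontinuation.
* `hosp_rate = 0.2`/patient-year, stay length 1 + Poisson(6) days;
  `death_rate = 0.004`/year.
* `good_implementation_rr = 0.9` with `p_good_generic = 0.78`: each patient
  draws a latent good/poor implementer class
  (`P(good | brand) = rr × p_good_generic`); good implementers refill
  on-time/early (delay U{−3..0} ⇒ CMA7 = 1), poor implementers refill late
  by ≥ 28% of the previous supply (per-interval coverage < 0.81 ⇒ CMA7 <
  0.9 on every eligible window). Set `good_implementation_rr=None` to use
  the shared delay distribution for everyone.
* Small rates of prior study-drug use, corticosteroid use, exclusion
  diagnoses, under-age patients and (optionally) switchers exercise every
  cohort filter; ground truth (group, planned cycle, death day, class) is
  exported per patient.

**What the generator does not emulate**, and hence what passing tests do
not establish about real claims: informative censoring and unmeasured
confounding (class and cycle are independent of covariates given group, so
IPTW is correctly specified by construction); seasonality and calendar
effects beyond the initiation-year marginal; dose changes, partial fills
and stockpiling behavior beyond the uncapped carry-over; real ICD-10/ATC
coding breadth; re-initiation after discontinuation.

**Calibration (parameter-recovery) conditions.** `recovery_study_params`
switches to all-1-month packages, no hospitalizations and no prior use.
Two mechanical couplings motivate this: (i) a 3-month package dispensed
late in follow-up leaves a censored tail that can push a latent-good
patient below CMA7 0.9, and (ii) hospital days add coverage that can lift
a latent-poor patient above it. Under the calibration conditions the latent
class determines the measured class deterministically. Because poor
implementers' late refills lengthen calendar persistence, 6-month
eligibility is not independent of class, so the eligible-subset marginal RR
is not the per-patient parameter; likewise the per-cycle geometric does not
induce an exactly proportional subdistribution hazard. CI coverage is
therefore assessed against pseudo-true values taken as the geometric mean
of the replicate estimates (Monte-Carlo error ≈ 14× smaller than one
replicate's CI half-width), with effect *direction* checked against the
parameters. At 200 replicates of n = 3,000 the suite observes coverage
0.945 (HR, pseudo-truth ≈ 1.16) and 0.965 (RR, pseudo-truth ≈ 0.86) with
100% correct signs; the acceptance test asserts coverage within 3
Monte-Carlo SEs of 0.95 and > 80% correct signs.

## Problem sizes

The shipped test suite uses: 200 × n = 3,000 replicates for recovery,
n = 5,000 for the balance property, 1,000 random episodes for the CMA7
oracle, 200-patient instances for the Fine–Gray/Cox equivalence, and
n = 300–6,000 elsewhere — sizes at which every Monte-Carlo tolerance above
has ≥ 3σ headroom. `scripts/acceptance.py` runs one n = 5,000 pipeline.

## Known limitations

* The Fine–Gray sandwich treats both the IPTW weights and the censoring KM
  as fixed; neither estimation stage propagates into the variance (the
  usual convention, slightly conservative for IPTW).
* Single-covariate effect models: the group indicator is the only regressor,
  as in the weighted-analysis design; covariate-adjusted outcome models are
  out of scope.
* The refill-gap rule evaluates the gap to the *next* event only; a patient
  alternating between early and very late refills is handled per event,
  with no smoothing across gaps.
* Percentages in rendered tables use half-up rounding at one decimal;
  χ² tests are computed without continuity correction and rank-sum tests
  with the normal approximation, so reported p-values are reproducible but
  may differ in the last digit from exact-test software.
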