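# Methods

## The index

A dispensed medication's 7-character ATC code is mapped to at most one of 46
disease categories by longest-prefix matching, so a specific entry
(`N05AN` → bipolar disorder) can carve an exception out of a broader one
(`N05A` → psychotic illness). Each active substance belongs to one category
only; codes outside the index are retained as evidence that the person-year
was observed, but carry no category. The packaged mapping is a
reconstruction of the published 46-category list with representative ATC
prefixes; any file with columns `atc_prefix, category_id, category_name`
can replace it, and loading rejects a prefix assigned to two categories
(which would make full codes ambiguous).

Severity weights are recalibrated per calendar year t: a logistic
regression of death in t+1 on all 46 category indicators, sex, and age
(continuous, in years — the published description says only "sex and
age-adjusted"; a linear term is the most conservative reading) over persons
aged ≥ 50 who filled at least one prescription in year t. The category
coefficient's exponent and two-sided Wald p-value pass through the step
function

| condition | weight |
|---|---|
| p > 0.10 | 0 |
| OR < 1.00 | −1 |
| OR ∈ [1.0+0.2(k−1), 1.0+0.2k), k = 1…5 | k |
| OR ≥ 2.00 | 6 |

The printed rule lists closed two-decimal bands (1.00–1.19, 1.20–1.39, …);
half-open intervals close the gaps between printed edges without overlap,
making the function total. Categories with a zero cell in their
exposure × death 2×2 table would separate the likelihood; they are dropped
from the model and reported with weight 0 and a warning, keeping the weight
table total over all categories. With a single category and constant
adjusters the fitted OR equals the closed-form cross-product ratio exactly,
which the tests verify to 1e−6.

A person-year's score is the sum of that year's weights over the distinct
categories filled (set semantics: repeat fills are irrelevant, and the
tests assert idempotence under duplicated dispensing rows). Person-years
with no index fill have a *missing* score — a first-class state carried
through banding, modelling, and the sensitivity analyses, never coerced to
zero at this layer.

## Cohort and person-time

Follow-up runs January 2006–December 2017. A person enters on January 1 of
the later of 2006 and the year they turn 51, must have filled at least one
prescription during 2005–2016, and is excluded entirely by any fracture in
the 1994–2005 washout history (so registered events are first fractures).
Each person × calendar year at risk becomes one slice whose exposure is the
score of the *preceding* year, banded ≤ 0, 1–5, 6–10, 11–15, 16–20, 21–25,
> 25, missing.

Dates carry month resolution only, so the package adopts the convention
that an event or censoring in month m contributes m/12 person-years — the
event month counts as time at risk. A fracture and a death recorded in the
same month count as a fracture. Person-time conservation is checked against
an independent month-count oracle per person, and events against the count
of distinct in-cohort first fractures.

## Rates

Slices aggregate exactly (no rounding) into
sex × birth-year × calendar-year × band cells. Incidence rates per 10,000
person-years are directly standardized over birth-year × calendar-year
strata. Because attained-age group is a deterministic function of birth and
calendar year, the default standard is the cohort's person-time
distribution *within each age-group margin* (sexes and bands pooled); a
global standard would have no overlap with any age-stratified target group.
Stratum variances treat event counts as Poisson; the 95% CI is a normal
approximation on the rate scale, floored at zero — adequate for the
well-populated strata this summary is used for, and the model-based
analyses, not these intervals, carry the inferential weight. The
median comparison is Mood's test (chi-square on counts above/below the
pooled median, continuity-corrected, ties counted below), the classic
reading of a "non-parametric equality-of-medians test".

## Count models

All model-based analyses are NB2 negative-binomial regressions — variance
μ(1 + αμ) — of event counts with a log person-time offset, the standard
response to overdispersion in rate data; α → 0 recovers Poisson. Birth year
and calendar year enter as centered continuous linear terms by default
(`adjust="categorical"` switches to full factor parameterization, useful at
registry scale). IRRs are exponentiated coefficients with Wald 95%
intervals; the reference band (≤ 0) is reported with IRR exactly 1. The
missing band is kept in all main fits as its own indicator. Offset-model
equivalence (identical estimates from person-level slices and aggregated
cells) is asserted in the tests.

Numerical choices: fits start from the Poisson MLE with α = 0.05 and use
BFGS, retrying with Nelder–Mead. When the NB likelihood is indistinguishable
from Poisson the information matrix is singular at the α = 0 boundary, so
coefficient inference falls back to the exact Poisson Newton fit with the
boundary α reported (this also makes saturated closed-form cases, like the
two-cell crude IRR of 4.0, exact). When α is weakly identified (likelihood
gain under 2 log-units) but the curvature is unusable, Poisson coefficient
inference is used with a logged warning; a genuinely divergent fit raises,
reporting the last log-likelihood. Bands with no events or person-time
cannot support a finite rate ratio and are dropped with a warning.

Derived analyses: likelihood-ratio tests for exposure × modifier
interactions (sex, birth year, calendar year); women-vs-men IRRs within
band × age-group strata; per-disease-category IRRs from one
exposure/outcome year pair (all category indicators simultaneously,
person-level, persons in no category forming every reference group);
latency analyses re-using one exposure year for outcomes 1, 3, 5 years
later with bands above 15 collapsed (sparse top bands), risk sets excluding
anyone fracturing or exiting before the outcome year; and two
missing-score sensitivity variants — reassigning missing slices of persons
under 70 to the reference band, or dropping missing slices.

## The synthetic registry

The generator emulates the *structure* of linked national prescription and
fracture registries, not Norwegian drug-utilization frequencies. Per
person: sex (55% female), baseline age uniform 50–95 (all three
attained-age groups populated), a standard-normal frailty scaled by
`frailty_sd` (default 1.0). Per calendar year 2005–2016, each of ten
default categories is filled with logit-linear probability in frailty and
age, with Markov persistence 0.7 (a fill repeats next year with that
probability, else is redrawn — so profiles drift slowly, which is what
makes latency attenuation testable; persistence 1 with no non-filler years
freezes profiles). A configurable 14% of person-years have no index fill —
the share of the study population *not* filling an index medication in a
year — implemented exactly: empty category draws in filler years are
topped up with one category sampled by the person's fill odds. Death in
year t+1 is Bernoulli with logit-linear dependence on the year-t category
indicators (the configured true mortality ORs — so calibration is checked
by parameter recovery), sex and age; month uniform. First fractures follow
a piecewise-constant yearly hazard, log-linear in the *previous* year's
true score (the weight-sum implied by the true ORs), age (+8%/year) and
sex (female ×1.8), with baseline 30 per 10,000 person-years and rate ratio
1.07 per score unit; fracture months are uniform within the year (month is
the finest resolution the data model records). A 3% washout-history rate
and small emigration rate exercise the exclusion and censoring paths; an
optional absorbing institutionalization state (default off) suppresses
dispensing records while risk continues, mirroring the known limitation
that institutional medication use goes unrecorded.

Default category prevalences (4–35%) and true ORs (0.7–2.5) were chosen to
span all weight bands away from band edges and to give every category
enough exposed deaths for stable calibration at the sample sizes the tests
use. Because the default ORs sit mid-band, calibrated weights equal the
true weights with high probability, so end-to-end recovery of the fracture
trend is clean; ORs near band edges would add benign weight-banding noise.

What passing tests therefore show: the pipeline recovers known generating
parameters (calibration ORs, per-unit fracture rate ratio, female rate
ratio, latency attenuation) from data with realistic missingness,
censoring, and confounding by age and sex. What they do not show: fidelity
to real registry idiosyncrasies — drug-specific fill patterns, secular
utilization trends, institutionalization dynamics, or diagnosis-specific
fracture mechanisms — and no resemblance of synthetic category prevalences
to any real population is claimed.

## Problem sizes

The recovery suite runs the full pipeline at 50,000 persons × 13 years per
replicate (20 replicates), calibration checks at 100,000, and latency
properties at 100,000 — sizes at which calibration noise is a small
fraction of effect sizes while the whole suite stays fast on one CPU.

## Known limitations

- The ATC prefix list is illustrative; real analyses should supply the
  validated mapping file for their registry.
- Standardized-rate CIs ignore between-stratum weight estimation error.
- The dispersion α is weakly identified in sparse strata; the package then
  reports Poisson-backed inference with a warning rather than failing.
- Competing risk of death is handled by censoring, matching the original
  design, not by subdistribution methods.
- Second and later fractures are out of scope by design.
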