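# Methods

## The decision problem

`taicea` models the lifetime costs and quality-adjusted life years (QALYs)
of two bowel-management strategies for spinal-cord-injury (SCI) patients
with neurogenic bowel dysfunction (NBD) in a Japanese payer setting:
transanal irrigation (TAI, the Peristeen system) offered after failed
standard bowel care, versus continuing standard bowel care (SBC).  The
primary outputs are per-arm discounted cost and QALY totals and the
incremental cost-effectiveness ratio (ICER), compared informally against
the 5-million-yen-per-QALY willingness-to-pay figure reported for Japan.

## Markov cohort model

Six states: TAI responder, TAI non-responder, resume-SBC (withdrawn
non-responders), SBC, stoma, dead.  The cohort enters the TAI arm split
60/40 into responders/non-responders; the SBC arm starts entirely in SBC.
Cycle length is 6 months; the "lifetime" horizon is realized as simulation
from the cohort start age (51.46 years) to age 110 with an absorbing dead
state.  Key transitions per cycle:

- responders persist on TAI (no withdrawal, no stoma risk);
- non-responders withdraw to resume-SBC with probability 0.60 per cycle
  (an alternative "all withdraw after the first cycle" mode is a config
  switch);
- resume-SBC and SBC face a stoma-construction probability of 0.00033;
- the stoma state is absorbing except to death;
- death claims every living state first within a cycle, with competing
  transitions scaled by (1 − q).

Costs and QALYs accrue on the occupancy of each lived cycle and are
discounted at 2%/year evaluated at cycle end; an optional half-cycle
correction flag moves the discount point to mid-cycle.

### Mortality

The underlying study is silent on survival, so background mortality is a
replaceable data file.  The packaged table
(`data/life_table_stylized.csv`) is a stylized Gompertz–Makeham curve,
q(x) = 2·10⁻⁴ + b·e^(0.094x) with b = 2.2·10⁻⁵ (men) and 1.05·10⁻⁵
(women), chosen to approximate recent Japanese all-cause mortality (life
expectancy ≈ 33 further years for a 51-year-old man).  Cycle death
probabilities are sex-weighted by the cohort male fraction (0.783) and an
SMR multiplier (default 1.0) scales the whole table.  Because the real
analysis's survival assumption is unknown, absolute QALY totals here
(11.40 vs 10.05) differ from the published 11.80 vs 11.00; the incremental
cost (≈3.27M yen at the 18 000-yen fee) and the cost-effectiveness
conclusion are insensitive to this choice.

### Per-cycle accruals

State costs sum, per person-cycle: treatment base cost (device cost/2 +
procedure fee × 6 for TAI states; SBC cost × 6 for SBC-type states; stoma
management by tenure — first year vs later — for the stoma state), plus
expected event costs: UTI rate × the treatment-split-weighted episode cost
(0.086 hospitalized / 0.811 outpatient / 0.103 untreated), hospitalization
rates × unit costs (decubitus and other separated), and nursing-visit rate
× weekly nursing cost × 26.  Weekly nursing cost is 2 visits × 5800 yen +
one 5200-yen long-hours premium.  Stoma entry triggers a one-off weighted
surgery fee (113 955) plus surgical hospitalization (239 020) in the entry
cycle.  QALYs per cycle are state utility × 0.5 minus one-off decrements
(0.060 per UTI, 0.010 per hospitalization), floored at −0.5.

Two conventions deserve emphasis:

- **Hospitalization recall period.** The calibrated hospitalization counts
  (e.g. 1.73 "other" admissions per SBC patient) carry no stated period
  and are implausible per 6-month cycle.  They are treated as counts over
  `hospitalization_recall_years` (default 8.5 years, the mean time since
  diagnosis in the TAI source cohort) and divided into per-cycle rates.
  This is a loudly documented config knob.
- **Stoma event rates.** The stoma state keeps SBC-level UTI,
  hospitalization and nursing rates by default (switchable to
  management-costs-only).

## Utility mapping

Per-dimension multinomial-logit models of the five EQ-5D-5L levels on NBD
score (covariates: age, gender) are fitted by maximum likelihood
(statsmodels MNLogit, reference level 1).  Expected utility at each
integer NBD score 0–47 is estimated by Monte Carlo (default 10 000 trials
per score): per trial, one uniform draw per dimension selects a level
through the cumulative probabilities (the 5-branch case expression,
implemented as a cumulative search), and the profile is valued with an
additive tariff.  Streams are keyed by (seed, score), one independent
uniform per dimension per trial, so each score is reproducible in
isolation.  The exact expectation over all 3125 profiles is computed by
enumeration as a cross-check; the MC estimate converges to it at 1/√trials.

The packaged tariff (`data/value_set_stylized.csv`) is a stylized additive
value set — full health 1.0, nonnegative per-dimension level decrements,
worst state −0.24 — because no Japanese EQ-5D-5L tariff is available to
the package; a real tariff in the same CSV layout drops in without code
changes.  Simulation covariates are fixed at the cohort means (age 51.46,
male), since the original covariate handling is unstated.

The base case uses the calibrated state utilities directly (0.533
responder, 0.470 non-responder, 0.479 SBC, 0.564 stoma);
`state_utilities_from_curve` derives alternatives from a mapped curve by
looking up round-half-up shifted scores (e.g. 16.74 − 6 → 11).

## Risk models

- `relative_risk` is the plain rate ratio (0.195/0.512 = 0.381 for UTIs).
- The stoma incidence rate is the exponential MLE λ = events/person-years
  on time-to-stoma data with non-event respondents censored at their
  disability duration; per-cycle probability 1 − exp(−λ/2).  The engine's
  default 0.00033/cycle is the calibrated value; the estimator exists to
  regenerate it from survey-style data.
- The nursing-visit indicator is a logistic regression on NBD score, age,
  gender and hand function.  The engine consumes the calibrated rates
  (0.318 SBC, 0.1941 responder) directly; the regression is the
  re-derivation path.

## Productivity scenario

Human-capital costing: employment rate (0.488) × age-band monthly wage ×
6 months × loss fraction, where the loss fraction is absenteeism by NBD
severity (0 minor / 0.0221 moderate / 0.0701 severe) or absenteeism +
presenteeism capped at 1 (0.17/0.3636/0.3971 presenteeism).  States map to
severities via their NBDS: SBC-type states at baseline 16.74 (severe),
responders at 10.74 (moderate), non-responders at 17.74 (severe); the
stoma state is kept severe since post-stoma NBDS is unstated.  Ages below
50 reuse the 50–54 wage band (only reachable in user-modified configs);
there is no retirement cutoff because a 70+ band exists.  Whether
presenteeism should be scaled by time-at-work before adding is unstated;
the capped sum is used.

## Sensitivity analysis

**One-way (tornado).** Each scalar parameter is run at ±20% of base, all
else fixed; probabilities are clamped to [0,1] with a flag recorded.
Parameters are ranked by |ICER_high − ICER_low|.  A side whose QALY
increment turns non-positive has an infinite numeric ICER (dominated
direction); ties — in particular ties at infinity — are broken by the
swing in net monetary benefit at a 5M-yen willingness to pay, which is
always finite, making the ranking invariant to listing order.  Under the
base calibration the responder utility ranks first: its −20% side pushes
responder utility below the SBC utility, the same "unrealistic worst
case" the underlying analysis remarked on.

**Probabilistic.** Parameters are drawn jointly and independently — gamma
for costs and unbounded nonnegative rates (method of moments: shape 1/cv²,
scale mean·cv²), beta for probabilities and utilities (method of moments
from mean and sd = cv·mean, with sd shrunk to 99% of the feasibility bound
when infeasible).  No standard errors are reported for the calibration, so
a common coefficient of variation of 0.2 mirrors the ±20% deterministic
range; it is configurable per parameter.  Correlations are not modelled.
Draw k uses an RNG stream keyed by (seed, k), making the PSA
bit-reproducible and embarrassingly restartable.  The CEAC reports, for
each willingness-to-pay w on a 0–10M grid (100k steps), the fraction of
draws with w·ΔQALY − ΔCost ≥ 0.  With cv → 0 every draw collapses to the
base case exactly.

Because utilities are drawn independently, roughly a quarter of draws
invert the responder/SBC utility ordering and lose QALYs — a direct
consequence of the wide, correlation-free distributional assumptions, not
a model defect.

## Synthetic survey generator

The generator emulates the 217-respondent calibration survey: age
truncated-normal (51.46, 13.50) on [19, 87]; 78.3% male; NBD score drawn
hierarchically — severity category first (10.2% minor, 19.5% moderate,
66.3% severe, 4% ineligible below-minor, matching the published mix after
the eligibility filter), then the integer score from the truncated normal
(16.74, 5.72) conditioned on the category bounds.  A single truncated
normal cannot match both the printed moments and the printed severity mix
(it yields ~74% severe); the hierarchical draw reproduces both.

EQ-5D-5L levels come from a true multinomial-logit model with an
adjacent-level structure: the logit of level k vs 1 is (k−1)·(α_d +
β_d·NBDS + 0.002·age + 0.05·male) with per-dimension slopes β_d of
0.030–0.045 per step, so worse NBDS moves mass monotonically toward worse
levels and the mapped utility curve decreases in NBDS.  The nursing-visit
indicator uses true logistic coefficients (NBDS slope 0.1102) calibrated
so predictions at scores 16.74 and 10.74 land near the published 31.8%
and 19.41% rates.  Hand impairment is Bernoulli(0.35).  Employment is
Bernoulli(0.488); absenteeism/presenteeism are beta draws (concentration
20) around the category means for the employed.  Time-to-stoma is
exponential (default hazard 0.00066/yr, matching 0.033%/cycle) with
administrative censoring at a gamma-distributed disability duration (mean
15 years, shape 2).

What the generator does **not** emulate: the real survey's HUI3 and WPAI
instruments, item non-response, within-respondent correlation beyond the
shared NBDS dependence, and any joint structure among employment, hand
function and severity.  Parameter-recovery tests passing on this generator
therefore show the estimators are correct under the assumed dependence
structure, not that the real survey would yield the published
coefficients.

## Numerical choices and problem sizes

- Occupancy conservation is enforced to 1e-12 per transition row.
- Lifetime runs are 118 half-year cycles; both arms run in ~20 ms.
- Test-suite simulation sizes: parameter recovery at n = 5000 (mapping,
  nursing) and n = 10 000 (stoma hazard, at a 0.01/yr test hazard so the
  expected event count supports a 10% tolerance); PSA tests at 200 draws;
  the acceptance script uses 5000 PSA draws.
- Monetary inputs are integer yen; accruals are floating point; JSON
  outputs round totals to whole yen.

## Known limitations

- Absolute lifetime QALY/cost totals depend on the stylized life table and
  the hospitalization recall convention; both are replaceable inputs, and
  the headline conclusion (positive QALY gain at an ICER in the low
  millions of yen, under the 5M benchmark) is robust across the three
  procedure-fee levels.
- The stylized tariff makes mapped utility levels comparable only in
  shape, not in absolute value, to tariff-based results.
- PSA ignores parameter correlation; the CEAC's lower tail is accordingly
  pessimistic.
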