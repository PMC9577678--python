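# Methods note

This note records the model as implemented: its assumptions, the calibration
of every default, the numerical choices, and what the synthetic data can and
cannot establish.

## Model structure

The simulation is a population-level cohort model, not a microsimulation of
individual trajectories. Within a year, averted quantities are linear in the
effect sizes and in baseline utilization; all dynamics across years enter
through exponential growth of stratum populations and per-capita
expenditures. Benefits accrue only in the year of meal receipt unless the
carryover option is enabled. Outcomes outside the model — emergency
department use, nursing-home admission, mortality, quality of life — are
deliberately not modeled: the intervention evidence base is too thin to
parameterize them.

## Synthetic population

The generator emulates the 2019 MTM-eligible population (adults with ≥1
diet-sensitive condition and ≥1 IADL limitation, insured by private plans,
Medicare, Medicaid, or both) from published calibration targets only.

- **Stratum counts** (private 1,485,365; Medicare 2,571,562; Medicaid
  697,292; dual 1,555,779; total 6,309,998) are taken from the published
  one-year results table.
- **Per-stratum baseline means are back-derived**, because they are not
  published directly: mean = published central averted amount ÷ (pooled
  effect × stratum N). This reproduces the published central stratum results
  exactly and yields overall weighted means — $31,132 expenditures, 0.5375
  hospitalizations — that agree with the published overall moments ($31,134,
  0.54) within printing precision. We do not rescale to the overall moments:
  doing so would shift every stratum result by ~0.5% for no gain in fidelity.
- **Expenditures** are lognormal per stratum, moment-matched to the mean and
  SD (stratum SD = stratum mean × overall CV of 34,749/31,134). The family
  was chosen because the implied median, mean/√(1+CV²) ≈ $20.8K, closely
  matches the published median of $20,107; a moment-matched gamma is
  available via `expenditure_distribution: gamma`.
- **Hospitalization counts** are negative binomial (the published SD/mean of
  0.94/0.54 implies variance ≫ mean, ruling out Poisson), moment-matched per
  stratum with the overall CV.
- **Expenditures and counts are coupled** by a Gaussian copula with rank
  correlation ρ = 0.5 (configurable). The joint distribution is not
  published; positive dependence is a modeling choice reflecting that
  high-utilization patients drive both margins. Totals and all headline
  results are insensitive to ρ (they depend only on weighted first moments);
  ρ matters only for record-level realism.
- **Diagnosis flags** are independent Bernoulli draws with a rejection step
  forcing ≥1 flag per record. Naive rejection would inflate conditional
  prevalences (e.g. diabetes 44.9% → 48.3%), so the input rates are
  pre-adjusted by solving the fixed point p_i = t_i·(1 − Π(1 − p_j)) so that
  post-rejection prevalences hit the published targets exactly. Comorbidity
  correlation is not modeled.
- **Weights** are uniform within stratum and scaled so they sum exactly to
  the stratum population — total weight is conserved for any record count.
- Age, sex, race and ethnicity, census region, ED visits are generated at
  published marginal distributions for descriptive realism only; the
  simulation consumes only weights, payer, expenditures, and
  hospitalizations.

The restricted populations (food-insecure 2017; diabetes-only; CHF-only)
have their own calibration tables built the same way from the corresponding
published subgroup rows. The CHF stratum counts sum to 1,695,283, eleven
persons below the published subgroup total; we use the stratum values.

**What passing tests show.** Calibration tests demonstrate that weighted
sample moments converge to the targets (within 3 SE at n = 50,000) and that
the pipeline reproduces the published headline estimates *given* those
targets. They cannot validate survey-design variance, comorbidity structure,
within-person dynamics, or any feature of the real microdata beyond its
published moments.

## Pooled effects

Study-level estimates are pooled by inverse-variance random-effects
meta-analysis with the DerSimonian–Laird moment estimator of τ² and
normal-approximation CIs (no Knapp–Hartung adjustment — the published CIs
are symmetric, consistent with the normal approximation). Hospitalization
effects are pooled on the log-risk-ratio scale and reported as percent
reduction (1 − RR); expenditure effects directly on the percent-change
scale. The study-level supplementary inputs are not published in the main
text, so the shipped defaults pin the pooled values — 19.7% (6.9–32.4%)
expenditure reduction, 47.0% (31.7–62.3%) hospitalization reduction, $9.30
(SD $0.64) per meal, 8 months of meals — and the study-record CSV template
(with two synthetic per-meal-cost records reproducing the pooled mean/SD
exactly) lets users substitute real study-level data.

## Costs

Annual per-person program cost = months_of_meals × monthly contract cost +
one screening per covered person per year.

- **Screening** ~ Uniform($27.34, $35.17), the published geographic range of
  Medicare reimbursement for an initial dietitian assessment (central
  estimate: the midpoint, $31.26).
- **Monthly contract cost $487.60** is calibrated: it is the value implied by
  the published total program cost (≈$24.8B = 6,309,998 × (8 × monthly +
  screening)). Notably, 10 weekly meals over 8 months at $9.30/meal
  (≈$3,225/person-year) does *not* reproduce $24.8B (≈$20.4B); the
  meals-per-month assumption behind the published total is unstated, so we
  anchor on the monthly contract cost and record the discrepancy rather than
  resolve it.
- **Monthly-cost draw SD $34.7** is calibrated so that, with independent
  per-stratum draws, the total program-cost 95% UI half-width is ≈7.5% of
  its mean, matching the published interval (23.1–26.8 around 24.8). The
  implied per-stratum cost CV (~7%) matches the published stratum intervals.

## Monte Carlo engine

- **1000 replicates**; estimates are replicate means; 95% uncertainty
  intervals are empirical 2.5th–97.5th percentiles with linear interpolation
  between order statistics (numpy's default rule).
- **Effect and cost draws are independent across strata within a
  replicate.** This is the single most consequential uncertainty choice. One
  shared national draw per replicate would give a total averted-expenditure
  UI of ±$25B and a cost-saving probability near 86%; independent per-stratum
  draws give ±$13B and ≈98%, matching the published intervals (±$14.5B) and
  the published ">97% of simulations cost saving". The published per-stratum
  UIs are consistent with the full pooled-CI spread, and their total with the
  √Σshare² aggregation of independent draws — which is what identifies this
  structure.
- **Truncation**: effect draws to [0, 1] (physical bounds), monthly cost at
  0. At ~3σ from the bounds, truncation shifts means negligibly.
- **Baseline uncertainty** enters by bootstrap: each replicate resamples the
  person table within stratum (with replacement, same size) and rescales
  weights to the stratum population. With a 50,000-record table this
  contributes less baseline variance than the original ~667-person survey
  sample would; our UIs are accordingly slightly narrower than the published
  ones. Survey design-based variance is out of scope.
- **Determinism**: one `numpy` Generator seeded from the caller's seed drives
  all draws; identical seed and configuration give bit-identical results.
  Multi-year runs derive per-year seeds from the master seed (year 0 reuses
  it, so a 1-year horizon equals the one-year engine exactly).

## Projection

Growth rates come from OLS of log(value) on year (`exp(slope) − 1`); the
shipped defaults are the published fitted rates. Historical series for
fitting are available synthetically (`synthetic_trend_series`) with
multiplicative lognormal noise — parameter-recovery tests (exact on
noiseless data, ±0.01 under 2% noise) stand in for real trend extraction.
Expenditure SDs grow with their means (constant CV). Base-year flows are
undiscounted; year *t* flows are divided by (1+r)^t — the base-year
convention is not published; this is our choice. Carryover recipients
(fraction f of the prior year's cohort) retain the prior year's expenditure
reduction at zero meal cost.

The cumulative 10-year *hospitalization* total follows the published value
closely (geometric-sum arithmetic lands within 0.1% of 18,257,000). The
cumulative 10-year *dollar* totals do not: the published $484.5B (3%
discounting) is ~9% above what the published year-1 values and growth rates
imply under this engine, and the published projection basis lives only in
supplementary material. We document the gap rather than tune toward it.

## Thresholds

Break-even solvers hold all other inputs at central estimates. The
expenditure-effect threshold is closed-form (program cost ÷ baseline
expenditures ≈ 12.6%, matching the published 12.7% within rounding) and is
cross-checked by bisection. The per-meal-cost threshold scales the monthly
contract cost linearly with the per-meal price, anchored at
($9.30, $487.60); under that scaling the solution is ≈$14.6/meal, which
diverges from the published $18.89 — the published figure is not derivable
from the published savings and costs under linear scaling, and we surface
the inconsistency instead of force-fitting it. The published diabetes-only
and CHF-only program-cost rows similarly imply a lower per-person cost
(~$2,970/year) than the primary population's (~$3,932/year) with no stated
basis; our subgroup runs apply the primary cost structure.

## Problem sizes and defaults

Default runs use 50,000 synthetic records and 1000 replicates — large enough
that generator sampling noise (~0.5% on baseline totals) is well inside
every reproduction tolerance, and a full one-year run completes in about a
second. All dollar values are 2019 USD; a `deflator` config key rescales
expenditures when mixing survey years (the published secondary-population
expenditures may embed an unstated inflation adjustment; we expose the knob
rather than guess the value).

## Known limitations

- Calibrated to published aggregates, not microdata: distributional results
  finer than weighted first moments inherit the generator's parametric
  assumptions.
- Effect sizes come from small, mostly observational studies pooled on an
  assumed scale; the model propagates their stated uncertainty but cannot
  repair bias in them.
- Program costs ignore geographic heterogeneity beyond the screening range,
  scale economies, and meal-production detail.
- The open cohort is an aggregate construct; no individual enters or exits,
  so duration-of-eligibility effects are not representable.
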