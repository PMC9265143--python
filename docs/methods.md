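# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort simulation with annual cycles
over a 25-year (effectively lifetime) horizon, entered at day 365 after
an index ischemic stroke at a mean age of 74. Seven day-365 outcome
categories (mRS 0–6) define the entry distribution; mRS 6 (died within
the first year) enters the absorbing stroke-death state at cycle 0, so
per-person results average over the full inception cohort while
first-year decedents contribute only their first-12-month inputs.

The engine state space doubles the six living mRS levels with a
post-recurrence flag (14 states in total). The flag exists purely to
keep the process Markovian: the relative risk of recurrence after a
first modelled recurrence (1.48) applies from the cycle after that
recurrence, without per-individual memory.

Within-cycle event ordering is not dictated by the published model
description, so it is fixed once and shared by the cohort recursion and
the microsimulation oracle: (1) other-cause death, (2) recurrent stroke
among survivors, (3) case fatality among recurrers, (4) redistribution
of recurrence survivors over equal-or-worse mRS levels. Patients cannot
improve their mRS level after the first year — a deliberate structural
assumption of the original analysis, carried over here.

Only recurrent-stroke events are modelled; other cardiovascular or
cancer events enter solely through background mortality. Background
mortality applies hazard ratios by mRS level (1.53 … 6.55) to the
age-indexed annual death probability on the log-survival scale,
`1 − (1 − q)^HR`, the exact transform under proportional hazards.

### Worsening on recurrence

The published description constrains post-recurrence destinations to
equal-or-worse states but gives no destination distribution. The default
worsening matrix redistributes survivors of a recurrence from level `k`
proportionally to the arm's day-365 living distribution restricted to
levels ≥ `k` and renormalised; any explicit row-stochastic matrix with
zero mass below the diagonal can be supplied in the configuration
instead.

## Economic accounting

Costs are 2018 AUD; costs and outcomes are discounted at 3%/yr starting
at cycle 1. First-12-month costs, QALYs and life-years are trial-level
inputs attached undiscounted at cycle 0, together with the per-patient
program cost ($2,959, intervention arm, both perspectives). No
half-cycle correction is applied by default (consistent with common
cohort-software practice); `settings.half_cycle_correction` enables a
trapezoidal variant for sensitivity use.

Interpretive choices worth flagging:

* "Year 1" management costs attach to the year of a modelled recurrence
  (the inflow into the post-recurrence layer), not to the first model
  cycle, because trial-based first-12-month costs already cover the
  index year. All other living person-time accrues "Year 2+" costs.
* Recurrence admissions are priced by destination mRS level; fatal
  recurrences by the mRS 6 admission cost ($10,886).
* Nursing-home costs accrue for all person-time in mRS 4–5 (no separate
  utilization probability is published); the "patients receiving nursing
  home care" tally counts cohort members ever occupying mRS 4–5.
* The healthcare perspective keeps medical care only (first-year
  healthcare costs, program, management, rehospitalisation); nursing-home
  and non-medical care are societal.
* Both discounted and undiscounted totals can be produced
  (`evaluate(..., discounted=False)`), since published summaries report
  both conventions in different places.

Dominance classification: *dominant* = no more costly and at least as
effective (at least one strict), *dominated* = the mirror image,
otherwise a finite ICER. The boundary case ΔQALY = 0 with ΔCost ≠ 0 is
classified by cost sign.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| Recurrence, year 1 / later | 0.0649 / 0.0201 | prob/yr | literature base case; year-1 value indexes the first model cycle |
| RR recurrence after recurrence | 1.48 | — | literature base case |
| Case fatality of recurrence | 0.1783 (alt 0.11) | prob | base case; low alternative used in one-way analysis |
| Mortality HR by mRS 0–5 | 1.53–6.55 | — | applied on log-survival scale |
| Utilities mRS 0–5 | 0.836–0.064 | — | EQ-5D at 12 months, held constant |
| Discount rate | 0.03 | /yr | local guideline convention; 0–5% in DSA |
| Horizon | 25 | yr | lifetime at entry age 74 |
| WTP | 50,000 | $/QALY | conventional local threshold |
| Cohort size | 10,000 | persons | reporting unit for tallies |

## Synthetic data generator

The generator supplies what is not public: per-arm day-365 mRS
distributions, a life table, and first-year inputs.

* **Control baseline**: Dirichlet draw (effective sample size 200)
  around the fixed synthetic reference shape
  (0.10, 0.13, 0.12, 0.12, 0.13, 0.12, 0.28 over mRS 0–6) — roughly 28%
  first-year case fatality and a heavy severe-disability tail, typical
  of elderly regional stroke cohorts. The shape was chosen once so that
  lifetime outputs land in a realistic range (per-person lifetime costs
  of order $10⁵, ≈4 discounted QALYs, ≈3,000/10,000 ever in
  nursing-home care); it is labelled synthetic and does not reproduce
  the trial's actual distribution.
* **Treatment effect**: the intervention vector moves a fraction
  `(0.26 − 0.17) × mrs_shift_per_treated` of each *living* category's
  mass one mRS level lower. First-year death is left untouched: the
  modelled mechanism is disability averted among survivors, and
  long-term event rates are identical between arms, so moving mass out
  of the death category would manufacture a disability-survivorship
  artifact (extra nursing-home person-time in the intervention arm) that
  contradicts the documented direction of effect.
  `mrs_shift_per_treated` defaults to 3.0 — about three one-category
  improvements per additional thrombolysed patient, a deliberately
  strong effect consistent with the large distribution shifts reported
  for thrombolysis delivered within 4.5 h. By construction the
  intervention arm first-order stochastically dominates the control arm
  toward less disability.
* **Life table**: Gompertz, `q(age) = 1 − exp(−a·e^{b(age−74)})` with
  a = 0.02, b = 0.09 (q(74) ≈ 0.0198, q(99) ≈ 0.17) — a stylized
  stand-in for national life tables; real tables can be supplied via the
  `life_table` configuration block.
* **First-year inputs**: the published 12-month means (costs
  $78,859/$76,954 societal; QALYs 0.53/0.38). No healthcare-perspective
  first-year cost is published, so it defaults to the societal value
  (synthetic stand-in). First-year life-years default to
  survival-weighted exposure, `1 − 0.5 × P(mRS6)`. An optional
  dispersion draws Gamma (costs) / Beta (QALYs) around the means.

What the generator does **not** emulate: correlation between baseline
severity and first-year costs, sex structure (no published parameter is
sex-stratified), secular trends in incidence or treatment, and
endovascular-thrombectomy benefits. Passing tests therefore demonstrate
the correctness and internal consistency of the machinery on realistic
synthetic inputs — not reproduction of the published lifetime totals,
which would require the unpublished trial distributions.

## Sensitivity analyses

* **One-way (tornado)**: ±20% of base for costs, probabilities and
  utilities (clamped to domains), the published 0.11 alternative for
  recurrence case fatality, a ±20% multiplier on the life table,
  discount rate 0–5%, horizon 10 years–lifetime. Published tornado
  figures do not state the ranges, so these are package defaults.
  Endpoints where the intervention is dominant/dominated have no ICER;
  they report net monetary benefit (NMB) at the analysis WTP, flagged,
  and rows are sorted by the NMB span, which is well defined across
  dominance boundaries.
* **Probabilistic**: independent parameter draws — a Dirichlet over the
  intervention arm's day-365 distribution (the one-year outcome
  uncertainty tested in the original analysis; concentration = baseline
  proportions × ESS, default 5,000, of the order of the modelled
  inception cohort), Betas for probabilities/utilities and Gammas for
  costs moment-matched with SE = 20% of the mean (no dispersions are
  published). Draw streams derive from one master seed via spawned
  substreams; degenerate (point-mass) distributions reproduce the base
  case bitwise. Invalid draws are resampled (bounded retries).
* **Threshold**: the per-patient program cost is replaced by the fixed
  implementation total ($1,762,892) divided by regional stroke volume
  `n`; cost-effectiveness (NMB ≥ 0) is monotone in `n`, so bisection
  finds the minimum viable volume, cross-checked by exhaustive scan in
  tests. On the synthetic fixture the minimum volume is of order
  60–70 patients/yr; the exact value depends on the generated baseline.

## Numerical choices

* Cohort conservation is maintained to 1e-12 per cycle (row-stochastic
  matrices built from exact complements).
* Life-table lookups clamp at the table's maximum age; ages below the
  table's range raise an error.
* The microsimulation oracle uses the same per-state probabilities and
  event ordering as the recursion; per state-cycle its occupancy counts
  are exactly Binomial(n, p) under the recursion's p, which is how the
  cross-engine agreement test calibrates its tolerance (exact binomial
  tails, family-wise 3σ across the grid).
* Degenerate inputs: `adjust_mortality` rejects p = 1; a worsening-matrix
  row with an empty tail keeps the patient in place; recurrence
  probabilities cap at 1.

## Problem sizes

Default analyses run a 25-cycle, 14-state recursion (milliseconds).
The packaged cross-checks use 200,000 microsimulated patients, 1,000 PSA
draws and 1,000 generator seeds — chosen to give tight Monte-Carlo
bounds while keeping the full suite around ten seconds.

## Known limitations

* Only recurrent stroke is modelled beyond background mortality.
* Utilities and long-term event rates are time-invariant.
* The synthetic baselines make headline lifetime totals
  fixture-dependent; published-value checks are restricted to quantities
  computable from published inputs.
* National scale-up treats per-patient incremental results as
  volume-independent, and the back-solved regional pools differ slightly
  from the published incidence chain (12,578 vs 12,634 at 100%
  eligibility); the discrepancy is surfaced in the output notes.
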