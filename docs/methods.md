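# Methods

`cryocea` re-implements, as a tested library, a published Markov cohort
cost-effectiveness analysis comparing ultrasound-guided breast cryoablation
(BCA) with breast-conserving surgery (BCS) for unifocal, small (≤ 1.5 cm),
node-negative, ultrasound-visible, low-risk breast cancer, from a US payer's
perspective.  This note records the model, its assumptions, the structural
choices that had to be made where the published description is schematic,
and what the tests do and do not establish.

## The cohort model

Four mutually exclusive health states: disease-free after primary treatment
(DF), local recurrence (LOCAL), distant recurrence / advanced disease
(DISTANT), and breast-cancer death (DEAD).  The cohort starts 100% in DF and
evolves over **5 one-year cycles** (mirroring the 5-year follow-up of the
cryoablation trial the clinical inputs come from) via a row-stochastic
transition matrix whose DF row is `[1−pL−pD−pM, pL, pD, pM]`.  Recurrence
states self-persist — a local recurrence is not re-treated and cannot return
to DF within the horizon, consistent with the exclusion of de novo second
primaries — and DEAD is absorbing.  There is no background (non-cancer)
mortality: the published model incorporates breast-cancer-specific mortality
only.

Rewards:

* **Costs.** At cycle 0 each arm pays its procedure cost plus
  `complication probability × complication cost`, undiscounted.  DF
  occupants accrue the routine annual care cost ($36,351/yr, which the
  source cost study states absorbs adjuvant therapy); recurrence states
  accrue costs per the calibrated structural flags below.
* **Utilities.** First-cycle DF utility is
  `u_first_year − treatment disutility − complication probability ×
  complication disutility` (0.696 − 0.02 − 0.024·0.05 for BCA,
  0.696 − 0.10 − 0.1432·0.05 for BCS); later DF cycles use
  `u_subsequent` = 0.779; LOCAL uses 0.779, DISTANT 0.685, DEAD 0.
* **Discounting.** Everything is multiplied by `(1.03)^(−k)` for cycle
  index k; cycle 0 is undiscounted and there is **no half-cycle
  correction** (back-calculation supports this: procedure + routine ×
  Σ discount factors ≈ the published BCA cost cell to a few tenths of a
  percent).
* Comparison metrics: net monetary benefit `NMB = WTP·QALY − cost` at
  WTP $100,000/QALY (subgroup re-analysis at $50,000), incremental
  cost-effectiveness ratio when the deltas share a sign, and explicit
  dominance/tie flags.

## Parameters and distributions

All inputs are `UncertainParam`s: a base value (the published point
estimate) plus a distribution for the probabilistic analysis — Beta for
probabilities, Gamma for costs (moment-matched: shape `(mean/sd)²`, scale
`sd²/mean`), Normal truncated to [0, 1] for utilities, and a point mass for
the two by-assumption disutilities.  The surgical complication risk is the
sum of three independent Beta components (wound 1.5%, hematoma/seroma
11.0%, infection 1.82%), capped at 1.

Two programmatic conventions:

* **Linear annualization.** Cumulative risks are divided by the follow-up
  years (4.3%/5 → 0.86%/yr), matching the source tables' arithmetic.  A
  constant-hazard alternative (`1 − (1−p)^(1/y)`) is retained as an option;
  for the ≤5% risks here the two agree within 10%.  (Note the constant-
  hazard value *exceeds* the linear one whenever the horizon exceeds one
  year — Bernoulli's inequality — not the other way around.)
* **Re-centring rule.** Several published Betas imply means that contradict
  the published point estimates (e.g. Beta(8, 186) implies 4.1% where the
  point estimate is 0.86%/yr — the Beta was evidently fitted to the 5-year
  cumulative count).  Whenever the disagreement exceeds 10% relative, the
  Beta is re-centred on the point estimate keeping its effective sample
  size α+β (Gammas would keep their coefficient of variation; none needed
  it).  The point estimates drive every published result, so they win.
  The low-risk surgery arm's recurrence is split 0.2%/yr local (the
  published one-way base) + 0.12%/yr distant, so the total reproduces 1.6%
  over 5 years under linear annualization.

## Structural calibration

The published state diagram leaves five readings open, encoded as
`VariantFlags`: local/distant recurrence cost timing (once on entry, every
cycle, or once on entry with routine care continuing), whether a
transition's rewards start in the entry cycle or the next, whether the
annualized routine cost is censored at death, and whether mortality acts
from all alive states or DF only.  All 72 combinations are enumerated and
scored by mean relative error against the six published base-case cells
(cost and QALY per arm and scenario) plus the published procedure-cost
break-even ($20,906, computed by the exact closed form: base cost + base
NMB difference).  Variants that cannot produce the four one-way crossings
the published sensitivity analyses display (over BCA mortality, local risk,
distant risk and procedure cost, within their printed sweep ranges) are
discarded first — notably, charging a local recurrence *only* `$36,351`
(once or per cycle) makes it no worse than staying disease-free, so the
local-risk sweep could never cross.

Top of the score table (full table reproducible via
`cryocea.calibration.calibrate()`):

| lr_cost_mode          | dr_cost_mode          | event_timing | dead_accrues_routine | mortality_source_states | feasible | score  |
|:----------------------|:----------------------|:-------------|:---------------------|:------------------------|:---------|-------:|
| on_entry_plus_routine | per_cycle             | entry_cycle  | True                 | all_alive               | True     | 0.0354 |
| on_entry_plus_routine | per_cycle             | entry_cycle  | True                 | disease_free_only       | True     | 0.0356 |
| on_entry_plus_routine | on_entry_plus_routine | entry_cycle  | True                 | all_alive               | True     | 0.0409 |
| on_entry_plus_routine | on_entry_plus_routine | entry_cycle  | True                 | disease_free_only       | True     | 0.0412 |
| on_entry_plus_routine | one_time_on_entry     | entry_cycle  | True                 | all_alive               | True     | 0.0452 |
| (… 67 more rows)      |                       |              |                      |                         |          |        |

The winner — local recurrence charged once on entry with routine care
continuing, advanced disease charged per occupied cycle, entry-cycle
rewards, routine cost not censored at death, mortality from all alive
states — ships as the `VariantFlags` defaults.  Its base case: BCA
$177,520 / 3.517 QALY; BCS $191,988 / 3.469 (low-risk) and $201,197 / 3.412
(1–20 mm); procedure-cost break-even $21,730 (+3.9% vs published).

## Probabilistic sensitivity analysis

Each iteration draws every uncertain parameter, reruns both arms, and
compares NMBs.  Parameters whose economic-table rows are identical across
arms (all shared costs/utilities plus the complication cost) are drawn once
and applied to both — the standard "parallel cohorts" correlation;
independent sampling sits behind `shared_draws=False`.  One seeded
generator per run, fixed documented draw order, bit-identical reruns.
Draws are clipped to their unit's support; an arm's drawn event
probabilities are proportionally rescaled in the (practically impossible)
event their sum exceeds 1.  The CEAC grid is $0–$200,000 in $10,000 steps —
a reporting convenience; the published analysis reports only $100,000 and
$50,000.  At n = 10,000 the cost SDs (~$21k) and QALY SDs (~0.145) sit
within ~10% of the published SD cells.

## Deterministic sensitivity analysis

One-way sweeps, two-way preference maps and thresholds all work on
`f(x) = NMB_bca − NMB_bcs`.  Thresholds: a 65-point scan of the bracket
locates sign changes, then bisection shrinks the first crossing (from the
lower end) to `1e-6` of the bracket width; multiple crossings and
no-crossing outcomes are reported explicitly in the result status.
Thresholds on probabilities are reported as annual probabilities (5-year
equivalents follow by the linear convention).  Tornado bars evaluate `f` at
each parameter's 2.5th/97.5th percentiles by default (the published ranges
are unstated; explicit per-parameter overrides are the knob), skip point
masses with a warning, and sort by descending width.  For the composite
Beta-sum the percentile is approximated by summing component percentiles —
slightly wide, which is conservative for a tornado.  The follow-up-cost
analysis perturbs `bca.routine_cost_increment`, an additive per-cycle
surcharge on the cryoablation arm's routine cost above the shared base.

## Synthetic scenarios

`generate_synthetic_scenario(seed)` emulates *valid* inputs, not realistic
epidemiology: probabilities uniform on [0, 0.2] (sum ≤ 0.6 by
construction), costs log-uniform on [$100, $200,000], utilities uniform on
[0.3, 1.0], disutilities on [0, 0.2], discount rate on [0, 0.07], and a
uniformly random structural variant.  It exists to exercise engine
invariants (occupancy conservation, absorbing death, path-enumeration
equivalence, bisection-vs-grid agreement) under arbitrary readings; a green
property test therefore establishes algebraic correctness of the engine,
not clinical plausibility of any scenario.

## Numerical choices

* Bisection tolerance `1e-6 ×` bracket width on the abscissa; the achieved
  |NMB difference| at the root is reported.
* The engine's path-enumeration oracle (tests) agrees to 1e-10 relative;
  occupancy conservation is asserted at 1e-12.
* The grid oracle for the bisection property uses a 1001-point grid over
  100 forced-crossing synthetic scenarios (agreement within one grid step).
* Degenerate inputs: zero risks give the closed-form geometric series
  (Σ discount factors = 4.717098 at 3%); certain mortality with entry-cycle
  timing leaves only the cycle-0 utility contribution.
* Exact ties in NMB are reported as "tie" and count toward neither strategy
  in the PSA.

## Known limitations

* **Absolute QALY levels run ~4.5% below the published cells** (3.52 vs
  3.69 for BCA).  The offset is common to all 72 variants and has the
  signature of a half-cycle correction in the published model; the
  no-half-cycle reading was kept because it reproduces the published *cost*
  cells, which carry the decision.  QALY *differences* between arms — what
  the comparison depends on — land inside the published 0.01–0.09 band.
* **The published clinical-risk thresholds are steeper than a 5-cycle,
  four-state cohort can produce.**  The published 2.1%/yr mortality
  break-even implies ~14 discounted QALYs lost per excess death — more than
  the 4.7 discounted life-years the horizon contains — and the published
  low-risk QALY difference (0.01) is likewise unreachable given the ±0.08
  treatment-disutility gap.  Our thresholds (mortality 3.6%/yr, local
  21.5%/yr, distant 1.97%/yr) have the published ordering, uniqueness and
  order of magnitude, and the cost-side thresholds ($21,730 and $4,094/yr)
  reproduce the published values within 4% and 3%.
* The tornado ranking with quantile ranges cannot reproduce the published
  driver list (the shared local-recurrence cost moves the NMB difference by
  only ~$400); the published tornado evidently used wider, unstated ranges.
* No currency-year inflation adjustment, no country-specific tariffs, no
  time horizons beyond the configured 5 cycles, no microsimulation, and no
  EVPI — all outside this package's scope.
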