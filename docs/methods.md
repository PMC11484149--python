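# Methods

## Model structure

The model is a hybrid of a 52-week decision tree and a three-state Markov
cohort model, on a common 6-month cycle grid with half-cycle correction.

**Decision tree (two cycles, weeks 0–52).** Response is assessed at week 16,
i.e. 16/52 years into cycle 1. Before that point nobody's response status is
known, so all person-time in weeks 0–16 is valued at non-responder utility
and non-responder resource use, with the active arm additionally accruing
drug-acquisition, monitoring and drug-specific adverse-event costs. The
16–52-week discontinuation probability (6.9%) is applied immediately at week
16, together with the response split: the on-treatment responder share from
week 16 onward is `p_response_16w × (1 − p_disc_16_52w)`. At week 52 the
sustained-response probability is applied to that share, *conditional* on
both week-16 response and non-discontinuation; sustainers enter the Markov
`in_response` state. With the base-case inputs the maintenance entrants
(before mortality) are 0.429 × 0.931 × 0.806 = 0.322 (active) and
0.107 × 0.725 = 0.078 (comparator).

**Markov phase.** Each cycle applies, in order: (1) background mortality to
both living states at the same rate, (2) exit from `in_response` to
`non_response`. The ordering matters only in the fourth decimal; applying
death first keeps the exit a pure treatment event among survivors. The exit
probability combines two independent competing risks per cycle:

* *waning*: `1 − W(t+Δ)/W(t)`, where `W` is the linear waning curve below;
* *discontinuation*: the annual probability converted to the cycle by the
  constant-hazard rule `1 − (1 − p)^Δ` (6.3%/year → 0.0320 per half-year
  for the active arm; zero for the comparator).

The cohort runs until the life-table maximum age (qx = 1 closes the table),
143 half-year cycles from the calibrated start age.

## Waning curve

`W(t)` falls linearly from 1 at week 52 to the long-term response rate at
`waning_horizon_years` after week 52, and is constant afterwards (floored at
0). Two readings of the long-term anchor were possible:

1. **conditional** — the anchor is the ratio of the long-term rate to the
   52-week sustained-response probability (W(h) = 0.62/0.806 = 0.77 for the
   active arm);
2. **absolute** — the anchor is the long-term rate itself, read as the
   fraction of maintenance entrants still responding (W(h) = 0.62).

The package uses the **absolute** reading. Under the conditional reading the
model keeps patients in response markedly longer than the published
deterministic results (years in response 4.07 vs 3.66; incremental QALY 0.86
vs 0.75, ~15% high); under the absolute reading every published deterministic
quantity is reproduced within about 3% (see `scripts/acceptance.py`). The
same comparison fixes the horizon pairing: the active arm wanes over 10
years and the comparator over 5, following the methods text rather than the
input table's (transposed) duration labels.

## Valuation

Person-time falls into three statuses — pre-assessment (weeks 0–16),
on-treatment responder, non-response — each with fixed annual rates
assembled in `valuation.status_rates`. Key conventions:

* **Subsequent treatment** (¥14,451/month) accrues on *all* non-responder
  person-time, including weeks 0–16, and is booked under
  `drug_acquisition`. Consequently "years receiving subsequent treatment"
  equals total life-years minus years in response, and the comparator arm's
  drug-acquisition row (its topicals cost ¥0) is exactly the discounted
  subsequent-treatment spend — both properties match the structure of the
  published results tables.
* **Utility after switching** is the comparator non-responder weight (0.61)
  regardless of original arm: states are treatment-defined, and the
  published QALY gap is consistent with this assignment, not with carrying
  the active arm's non-responder weight (0.78) after switching.
* **Adverse events** use the current treatment's annual rates (active-arm
  rates while on drug, comparator rates otherwise) times per-event
  management costs; no AE disutilities, per the source analysis.
* **Monitoring** applies only while on the active drug: ¥13,270 in model
  year 1, ¥490/year (1× renal/CBC/liver panel) thereafter.
* **Productivity loss** (societal perspective only) is
  employment × hours/week × 52 × wage × lost-hours share, where the share is
  33.6% at baseline/non-response and 33.6 − 23.4 = 10.2% for responders,
  clamped at zero, and prorated within the cycle that crosses the
  retirement age (65). Because the responder effect is an additive reduction,
  a shift in the *baseline* share moves both arms almost identically and
  largely cancels in the incremental cost; this is why utility weights and
  drug cost, rather than the baseline share, top this package's tornado.
* **Discounting** at 2%/year, factors evaluated at cycle midpoints;
  life-years are undiscounted (the published 46.05 total life-years is an
  undiscounted life expectancy; 2%-discounted survival would be ~40%
  smaller).

Accrual uses the mean of begin- and end-of-cycle occupancy. Test-only
`timing="begin"/"end"` switches exist to bracket the half-cycle-corrected
totals; the bracketing holds for life-years, QALYs and responder-dominated
cost components, but not necessarily for components that pay more per
non-responder year (resource use, lost income), where the exit-driven state
shift can outweigh the smaller end-of-cycle alive mass.

## Mortality and calibration

Annual death probabilities are looked up at the floor of the cohort age and
converted to cycles by the constant-hazard rule. The bundled synthetic life
table is Gompertz–Makeham, qx(a) = 1 − exp(−(A + B·e^{C·a})) with
A = 2×10⁻⁴/y, B = 3.2×10⁻⁶/y, C = 0.118/y, closed at age 110 — chosen to
give a remaining life expectancy of 46.6 years at age 38 and 84.0 years at
birth, the scale of the modelled adult population. It reproduces a realistic
*adult* mortality schedule only: no infant-mortality hump, no cohort
effects, no sex stratification.

The cohort start age is not stated in the source analysis;
`calibrate_start_age` tunes it so the model's undiscounted life expectancy
matches a target (46.05 years → start age ≈ 39). Under the floor-age lookup,
life expectancy is a step function of start age (two plateaus per year of
age at half-year cycles), so the bisection returns the left edge of the
plateau where life expectancy first drops to or below the target; targets
between plateau values are matched only to within the plateau step
(~0.2–0.5 y of life expectancy, well inside the tolerances used anywhere in
the package).

## Sensitivity analysis

Every varied input carries an uncertainty annotation (`default_uncertainty`):
the standard errors printed in the input table where available, otherwise
the 20%-of-mean convention. Distribution families follow support — beta for
proportions and utilities (method-of-moments from mean and SE; if the SE is
infeasible for the beta support the draw falls back to a uniform on the
clamped ±1.96·SE interval, with a logged warning), gamma (shape–scale from
mean and SE) for costs, frequencies and durations, normal for the signed
productivity effect and retirement age. After each joint draw,
cross-parameter invariants are repaired by clamping (long-term rate ≤
sustained-response probability; responder effect ≤ baseline share;
retirement age within [start age, max age]).

* **OWSA** sets each parameter to its bounds one at a time and reruns the
  deterministic model. `mode="ci"` uses mean ± 1.96·SE where an SE exists
  (the methods-text convention), `mode="fixed_fraction"` uses ±20%
  throughout (the tornado-figure convention); bounds are clamped to the
  family's support. Entries are ranked by ICER range.
* **PSA** draws all annotated parameters jointly (1000 iterations by
  default) and reruns both arms per draw; both perspectives are aggregated
  from the same draws. The headline mean ICER is the **ratio of means**
  E[ΔC]/E[ΔE] (standard for CEA, stable when ΔE crosses zero); the mean of
  per-iteration ratios is also exported because the source does not state
  which was used.
* **CEAC** is the fraction of iterations with positive incremental net
  monetary benefit λ·ΔE − ΔC at each willingness-to-pay point; default grid
  0 to ¥15M in ¥250k steps.

All randomness flows through a single `numpy` Generator seeded by the
caller; fixed seeds give byte-identical outputs.

## Verification design

An individual-level microsimulation oracle (`microsim_oracle`) replays the
identical event sequence with Bernoulli draws and values person-time through
the same `status_rates`, but shares none of the cohort-trace algebra. On
configurations with all probabilities 0/1 and a deterministic life table it
must (and does) match the engine to the last ulp; on stochastic
configurations at n = 200,000 individuals the engine lies within 3 Monte
Carlo standard errors of the oracle means. Property tests additionally check
occupancy conservation, dead-state monotonicity and cross-arm life-year
equality on 100 randomized-but-valid parameter sets, and weak dominance of
all discounted totals at a zero discount rate.

Problem sizes used by the default test run and the acceptance script: 143
half-year cycles per deterministic run, 1000 PSA iterations, 200,000
oracle individuals per verified configuration.

## What the synthetic inputs do and do not show

The synthetic life table and the stress parameter generator exercise the
model's algebra, accounting identities and sampling machinery; passing tests
demonstrate internal correctness and faithful reproduction of the published
aggregate results, not external validity. Real-world features deliberately
out of scope: multiple response levels (response is binary), re-treatment
after switching, excess disease mortality, AE disutilities, administration
and caregiver costs, comparators other than standard of care, and currency
inflation adjustment.
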