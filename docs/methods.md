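# Methods

`strokecea` evaluates the cost-effectiveness of the edaravone dexborneol
sublingual tablet (EDSL) against the concentrated solution for injection
(EDCSI) in acute ischemic stroke, from the Chinese healthcare-system
perspective, in 2024 CNY. This note records the model, its assumptions,
the defaults, and the design choices made where the design was genuinely
open.

## Model structure

A 90-day decision tree feeds a lifetime Markov cohort model.

**Decision tree (day 0–90).** Patients enter at stroke onset, receive the
14-day twice-daily course (tablet or 30-minute IV drip), and exit with a
day-90 modified Rankin Scale (mRS 0–6) distribution. The arm-specific
resource events of this window are: 28 dosing events (both arms), 28 IV
administrations (EDCSI only), weekly renal-function monitoring (urea
nitrogen + creatinine) over the 2-week course, one initial hospitalization,
and a one-time IV-drip disutility (EDCSI only).

**Markov model (lifetime).** Seven health states: mRS 0–5 and death, with a
reserved transient slot for recurrent-stroke event bookkeeping. Starting
age 60, cycle length 1 year, default horizon 40 cycles. The day-90
distribution is the initial state vector; cycle 0 is a bridging period that
holds that distribution for the remaining 275/365 of the first year with no
transitions and no discounting. In every later cycle, events resolve in a
fixed order:

1. **Death.** The age-specific all-cause annual probability `q(a)` is
   scaled by the state-specific excess-mortality hazard ratio on the rate
   scale: `p = 1 − (1 − q)^HR`. Defaults: HR 1.53, 1.52, 2.17, 3.18, 4.55,
   6.55 for mRS 0–5.
2. **Recurrence.** Survivors suffer a recurrent ischemic stroke with a
   year-since-stroke probability (5.9% in year 1 declining to 1.6% from
   year 10), applied uniformly across alive states. Recurrers move to a
   state of *equal or greater* disability: the post-recurrence destination
   distribution is truncated at the current state and renormalized, with
   mRS 6 mass adding to death. If the truncated mass vanishes (possible
   only for non-default destination distributions), the patient remains in
   place — rows are always stochastic.
3. **Stay.** Non-recurrers remain in their state.

Death-before-recurrence avoids double counting; the microsimulation oracle
in the test suite applies the same order, so the matrix construction is
checked against an independent individual-level implementation, not
against itself. Recurrence is a within-cycle event, not a persistent
occupancy state: expected recurrence counts per cycle (split by
destination band) feed one-time hospitalization costs and disutilities.
The year-since-stroke clock does not reset on recurrence.

Half-cycle correction credits each Markov cycle with the trapezoid of its
bounding occupancy rows. Ages beyond the life-table maximum reuse the last
available `q` (bounded extrapolation).

## Economics

All costs are direct medical costs, 2024 CNY. Unit costs: tablet ¥70
(gamma-distributed 63–77), vial ¥29.68 × 3 vials per administration, drip
¥8.11, renal panel ¥6.28 + ¥6.51 weekly × 2 weeks, hospitalization
¥12,995.74 / ¥17,744.26 / ¥14,373.51 for day-90 bands mRS 0–2 / 3–5 / 6,
post-stroke care ¥9,544.86 / ¥14,669.48 per year for bands 0–2 / 3–5.

* The initial hospitalization is charged once at entry, banded by the
  day-90 state; day-90 deaths take the mRS 6 band. The 10-day average stay
  is descriptive of that lump sum, not a per-diem multiplier.
* Each expected recurrence charges one hospitalization, banded by the
  destination state (mRS 6 band for fatal recurrences), discounted at its
  cycle.
* Post-stroke care cost accrues during the first post-acute year (the
  275/365 bridge window) on the day-90 distribution. Routine maintenance
  care in later years is outside the costing scope — the analysis prices
  stroke-attributable acute and first-year care plus per-recurrence
  hospitalizations. This is what keeps total costs on the ¥28k scale while
  QALYs accrue over the lifetime; an optional `lifetime_poststroke` switch
  instead accrues the banded annual cost on half-cycle-corrected occupancy
  every cycle, which raises totals to the ¥130k scale and, because the
  more effective arm survives longer, erodes its cost advantage.

QALYs use EQ-5D utilities by state (0.983, 0.894, 0.679, 0.556, 0.270,
0.058 for mRS 0–5; 0 when dead). The day-90 distribution is held over the
whole 90-day window (90/365 of a year, no within-window trajectory) and
the bridge window; later cycles use half-cycle-corrected occupancy. The
stroke disutility (0.086) is a one-time decrement per expected recurrence,
discounted at the event cycle; the drip disutility (0.023) is a single
decrement at time zero in the EDCSI arm only (it is not re-applied to
hospitalizations after recurrence).

**Discounting.** Both streams discount at 5%/year. The first model year
(tree + bridge) is undiscounted; the flow of year *t* ≥ 2 carries
`(1 + r)^−(t−1)`.

**Comparison.** ΔC, ΔE, ICER = ΔC/ΔE, dominance labels, and net monetary
benefit `λ·ΔE − ΔC` at willingness-to-pay anchors of 1× and 3× 2024 GDP
per capita (¥95,749 / ¥287,247). Equal effects leave the ICER undefined
and the label is decided on cost with an explicit marker.

## Treatment-arm comparability (sIPTW)

The two arms derive from different trials, so baseline characteristics are
adjusted by stabilized inverse probability of treatment weighting over 13
covariates: sex, smoking, drinking, NIHSS, prior stroke, stroke subtype
(large-artery, cardioembolic, small-artery, other; three indicator
contrasts in the model, four indicators in balance reporting),
hypertension, diabetes, hyperlipidemia, heart disease. Records missing any
baseline covariate are excluded before fitting.

* Propensity model: main-effects maximum-likelihood logistic regression
  (no interactions or splines); convergence requires gradient norm < 1e−6,
  and separation is surfaced as an estimation error.
* ATE weights (base case): treated `P(T=1)/e(x)`, control
  `P(T=0)/(1−e(x))`. ATT weights: treated 1, control
  `[e(x)/(1−e(x))]·[P(T=0)/P(T=1)]` — the treated sample stays unweighted,
  the standard ATT convention.
* No weight truncation by default; a percentile cap is available.
* Balance: weighted standardized mean differences, |SMD| < 0.1 judged
  negligible. Weighted mRS distributions are compared with a Pearson
  chi-square on counts rescaled to each arm's Kish effective sample size
  `(Σw)²/Σw²`; with unit weights this is exactly the classical test. The
  Kish choice is this package's own: it uses the precision actually
  present in the weighted sample rather than the inflated raw pseudo-count.
* Missing day-90 outcomes are redistributed proportionally over the
  observed weighted distribution (equivalently, renormalized to one).

## Synthetic data

Real trial IPD and the census life table are not deposited, so the
generator emulates them; its defaults are the conditions every test and
the acceptance script run under.

* **Cohort.** 1,500 patients/arm (phase-III scale; ~3,000 total).
  Covariate prevalences: sex 0.35, smoking 0.40, drinking 0.30, NIHSS
  ~N(8, 3²) rounded and clipped at 0, prior stroke 0.15, subtype
  (0.45, 0.08, 0.34, 0.13), hypertension 0.60, diabetes 0.22,
  hyperlipidemia 0.12, heart disease 0.10 — plausible for a Chinese acute
  ischemic stroke trial population.
* **Assignment.** Logistic in the covariates (mild confounding by
  indication, e.g. +0.04 log-odds per NIHSS point), intercept centered
  analytically so each arm receives ≈half the cohort.
* **Outcome.** Cumulative-logit (proportional odds) over mRS 0–6,
  `P(mRS ≤ k | x, T) = expit(c_k + τT − g(x))`, with severity `g(x)`
  sharing covariates with the assignment model (that overlap is the
  confounding). The six cutpoints were calibrated once, by solving
  `E_x[expit(c_k − g(x))] = target` over a 2×10⁶-draw covariate sample,
  so the control arm's marginal day-90 distribution is
  (0.320, 0.326, 0.120, 0.090, 0.070, 0.040, 0.034) — P(mRS ≤ 1) = 64.6% —
  and τ = 0.2226 lifts the treated marginal P(mRS ≤ 1) to 69.3%, the
  weighted proportions the analysis anchors on. ATT proportions follow
  from the same fit and are not separately calibrated.
* **Missingness** is completely at random (default 5% of outcomes),
  matching the proportional-redistribution remedy downstream.
* **Life table.** Gompertz, `q(a) = 1 − exp(−α·e^{βa})` with α = 3×10⁻⁵,
  β = 0.095 — about 0.9% annual mortality at 60, doubling roughly every
  7.3 years; a real census table drops in via the same two-column CSV.
* **Post-recurrence distribution.** Synthetic placeholder
  (0.08, 0.16, 0.18, 0.20, 0.15, 0.10, 0.13), shaped like a moderately
  severe recurrent-stroke outcome and fully configurable.

What the generator does *not* emulate: site and enrollment-period effects,
informative missingness, measurement error in mRS scoring, and any
covariate–treatment interaction. Passing tests therefore demonstrate the
machinery is correct under its stated assumptions, not that the clinical
anchors would reproduce on the real trial data.

## Uncertainty analysis

Parameters carry (base, lower, upper, family); the printed range is read
as a 95% interval, `SE = (upper − lower)/3.92`, and families are fitted by
method of moments (gamma for costs/rates, beta for utilities and
disutilities, lognormal for hazard ratios, uniform for discount rates).
Parameters tabulated without ranges (the recurrence schedule, the vial
price, hospital days) are fixed.

* **One-way DSA** re-runs the pipeline at each varied parameter's bounds,
  all else at base; entries are ranked by spread on the ICER, falling back
  to incremental NMB for any entry whose QALY increment changes sign
  between bounds (an ICER is not comparable across that flip). Failures at
  a bound are flagged, never dropped.
* **PSA**: 5,000 iterations, every non-fixed parameter drawn independently
  per iteration; invalid draws (e.g. a utility outside [0, 1]) are redrawn
  with a 1% rejection-rate abort. Day-90 mRS distributions are held fixed
  (a Dirichlet sampling option exists as a pipeline extension point);
  discount rates are sampled uniform(0, 0.08) because they carry a
  distribution in the parameter table.
* **CEAC**: share of iterations with `λ·ΔE − ΔC > 0` over a WTP grid of
  0–300,000 CNY in 5,000-CNY steps, covering both anchors.
* **Scenarios**: horizons of 90 days (decision tree only — no discounting,
  no recurrence) and 5, 10, 20, 30, 40 years, under both ATE and ATT
  weighting.

## Numerical contracts

* Trace rows sum to 1 within 1e−10 at every cycle; dead mass is
  non-decreasing; transition-matrix rows sum to 1 within 1e−12.
* mRS distributions validate to 7 non-negative entries summing to 1 within
  1e−12.
* Cost components sum to the per-arm total within 1e−6 (enforced at
  construction).
* One integer seed drives any run; generator, PSA and the test-suite
  microsimulation use independent derived streams, and identical seeds
  give bit-identical tables.

## Problem sizes used by the checks

The bundled acceptance script emulates the pooled two-trial cohort at
1,500 patients/arm, runs the full 40-year base case and scenario grid, and
a 5,000-iteration PSA. The test suite verifies matrix/microsimulation
agreement with 10⁶ walkers, weighting balance over 50 replicates of
2,000/arm, and effect-sign recovery over 100 replicates of 1,500/arm.

## Known limitations

* The anchor day-90 distributions, the life table, and the
  post-recurrence distribution are synthetic stand-ins; absolute cost and
  QALY totals shift with them, though the dominance finding is robust
  across the whole sensitivity grid under the defaults.
* Recurrence carries no tunnel states: recurrence risk depends on time
  since the *index* stroke only, and repeat recurrences within a cycle are
  not modelled.
* Monthly cycles, treatment re-administration on recurrence, adverse-event
  costs/disutilities, and indirect (societal) costs are out of scope.
* The chi-square weighting convention (Kish rescaling) is one defensible
  choice among several; the balance conclusions do not depend on it.
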