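# strokecea

Cost-effectiveness modelling of the edaravone dexborneol **sublingual
tablet (EDSL)** versus the **concentrated solution for injection (EDCSI)**
in acute ischemic stroke, from the Chinese healthcare-system perspective.

Both formulations share the same neuroprotective agent; the tablet trades
a 30-minute twice-daily IV drip for sublingual dosing. The question for a
payer is whether the tablet's convenience comes at an acceptable price per
quality-adjusted life-year. This package implements the full evaluation
pipeline for analysts who want to reproduce, audit, or re-parameterize
that comparison:

1. **Treatment-arm comparability** — the two arms come from different
   trials, so stabilized inverse probability of treatment weighting
   (sIPTW) over 13 baseline covariates aligns them; ATE weighting is the
   base case, ATT a scenario. Balance is judged by standardized mean
   differences (|SMD| < 0.1) and weighted chi-square tests.
2. **Decision model** — a 90-day decision tree whose endpoint, the day-90
   modified Rankin Scale (mRS 0–6) distribution per arm, seeds a lifetime
   Markov cohort model (start age 60, 1-year cycles, 40-year horizon) over
   states mRS 0–5 and death. Annual transitions combine age-specific
   all-cause mortality scaled by state-specific hazard ratios,
   `p = 1 − (1 − q)^HR`, with a declining recurrent-stroke schedule that
   moves patients to equal-or-worse states. Costs and QALYs discount at
   5%/year with half-cycle correction.
3. **Decision metrics** — incremental cost ΔC, incremental QALYs ΔE,
   ICER = ΔC/ΔE, dominance labels, and net monetary benefit
   `λ·ΔE − ΔC` against willingness-to-pay anchors of 1–3× 2024 Chinese
   GDP per capita (¥95,749–¥287,247).
4. **Uncertainty** — one-way deterministic sensitivity analysis (tornado
   ranking), 5,000-iteration probabilistic sensitivity analysis with
   method-of-moments gamma/beta/lognormal/uniform samplers, the
   cost-effectiveness acceptability curve, and a horizon × estimand
   scenario grid.

The real trial patient data and census life table are not public, so a
first-class synthetic-data module generates confounded two-arm cohorts
(proportional-odds day-90 outcomes calibrated so ATE-weighted
P(mRS ≤ 1) ≈ 69.3% vs 64.6%) and a Gompertz life table; real inputs drop
in via CSV at the same interfaces. See `docs/methods.md` for the model in
full.

## Worked example

```bash
$ strokecea weight --seed 1
ATE weighted P(mRS<=1): EDSL 0.713, EDCSI 0.649

$ strokecea run-base --seed 1
dCost -978.20 CNY, dQALY 0.5046, ICER -1,938.54 CNY/QALY -> dominant
```

With seed 1 the generator produces a 3,000-patient confounded cohort;
after sIPTW weighting, 71.3% of the sublingual arm versus 64.9% of the
injectable arm reach functional independence (mRS ≤ 1) at day 90. Run
through the lifetime model, the sublingual strategy costs ¥978 less and
yields 0.50 more QALYs per patient, so its ICER of −¥1,939/QALY marks it
*dominant* — more effective and less costly — and no willingness-to-pay
threshold is needed to recommend it. `run-base` also writes the
Table-style component breakdown (`base_case.csv`) and the covariate
balance report (`balance.csv`).

The same pipeline is available as a library:

```python
from strokecea import (CohortConfig, ModelPipeline, generate_trial_ipd,
                       generate_life_table, load_parameters,
                       weighted_day90_distributions, run_psa, compute_ceac)

ipd = generate_trial_ipd(CohortConfig(n_per_arm=1500, seed=1))
d_edsl, d_edcsi, balance = weighted_day90_distributions(ipd, "ATE")
model = ModelPipeline(d_edsl, d_edcsi, generate_life_table())
result = model(load_parameters().base_values())   # a CEResult
psa = run_psa(model, load_parameters(), n_iter=5000, seed=1)
curve = compute_ceac(psa)
```

Other CLI subcommands: `simulate`, `dsa`, `psa`, `ceac`, `scenario`
(`strokecea <cmd> --help`).

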