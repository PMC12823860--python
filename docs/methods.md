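# Methods

## Model structure

The package implements a hybrid decision-tree + Markov cohort model for
posterior circulation ischemic stroke treated 4.5–24 h after onset with
intravenous alteplase plus standard therapy versus standard therapy
alone.

**Decision tree (months 0–3).** Each arm is characterised by its
3-month modified Rankin Scale (mRS 0–6) outcome distribution and its
symptomatic intracranial haemorrhage (sICH) incidence. Quarter payoffs:

- life-years: `(1 − p[mRS6]) · 0.25` — survivors are credited the full
  first quarter, 3-month decedents none. The trial reports status at
  3 months, not death times; crediting survivors fully and decedents
  nothing is the symmetric simplification.
- QALYs: `Σ p[i]·u[i]·0.25 − sICH_incidence·d_sICH·0.25`. sICH enters as
  a one-time cost plus a one-quarter utility decrement only; sICH
  mortality is taken to be already embodied in the arm's 3-month mRS
  distribution, avoiding double-counted deaths.
- costs: acute hospitalisation by mRS level (decedents' hospitalisation
  is still incurred), one quarter of post-discharge care for survivors,
  sICH event cost, and the drug cost for the thrombolysis arm. Unit
  costs are identical across arms; arm differences arise only through
  the mRS mix, the drug cost and the sICH incidence.
- The quarter is treated as time zero and left undiscounted; at 5 %/year
  the alternative conventions differ by well under 1 %.

**Markov model (cycles 1–119).** States {mRS 0–5 alive, Dead}; cycle
length 0.25 y; horizon 30 y total (1 decision-tree quarter + 119 Markov
quarters, ages 64 → 94). Event ordering within a cycle: background death
first; recurrent stroke among survivors; recurrence fatality (case
fatality 0.21) nested within recurrence. This keeps the death flows
("after recurrent stroke" vs. "background") disjoint. Recurrence
survivors remain in their mRS state with probability
`p_stay_given_survive` (default 0.5) or shift exactly one state worse,
capped at mRS 5 — the minimal rule consistent with "remain or worsen";
both the probability and the rule's inputs are configurable. A second
recurrence in a later cycle is allowed implicitly; history is not
tracked.

**Mortality.** The age-banded life table (5-year bands from age 60;
ages beyond the last band reuse the "85-" rate; ages below the first
band use the first) gives annual probabilities converted to cycle
probabilities on the hazard scale,
`p_cycle = 1 − exp(−hr·(−ln(1−p_annual))·Δt)`, with `hr` the
mRS-specific death hazard ratio times a global post-stroke excess ratio
(default 1.0, range 1.0–1.2 folded into the mRS 0/1 hazard-ratio range).

**Payoffs and accumulation.** The half-cycle correction weights each
cycle's payoffs by the mean of start- and end-of-cycle occupancy
(trapezoidal rule); with the correction disabled, end-of-cycle occupancy
is used. Recurrence survivors spend the event cycle at the recurrence
utility 0.42/y, *replacing* (not multiplying) the state utility: under
the trapezoidal weighting their contribution `½(u_src + u_dst)` is
replaced by `u_rec` for that cycle. The recurrent-stroke event cost is
charged to all recurrence events, fatal ones included. Costs, QALYs and
life-years are all discounted by `(1 + r)^(−0.25k)` at cycle `k`
(r = 0.05/y, sensitivity range 0–8 %).

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| 3-month mRS distribution, both arms | trial values | probability | simplex-validated; renormalised on load if the sum is within 1e-3 of 1, rejected beyond |
| sICH incidence | 0.0172 / 0.0087 | probability | alteplase / standard |
| utilities mRS 0–6 | 0.95, 0.89, 0.67, 0.44, 0.16, 0.10, 0 | QALY/y | non-increasing enforced on strict load |
| recurrence utility | 0.42 | QALY/y | event-cycle replacement |
| sICH disutility | 0.38 | QALY | one quarter applied once |
| death hazard ratios mRS 0–5 | 1, 1, 1.11, 1.27, 1.71, 2.37 | — | OWSA ranges as printed; the mRS 2 low bound 0.89 crosses 1 and is swept untruncated |
| annual background mortality | 0.00760 … 0.15120 | probability/y | 5-y bands, 60–85+ |
| recurrence case fatality | 0.21 | probability | |
| annual recurrence mRS 0–5 | 0.02, 0.02, 0.04, 0.04, 0.06, 0.06 | probability/y | ASSUMED: monotone in mRS at secondary-prevention magnitudes |
| acute hospitalisation mRS 0–6 | 15–55 k, 20 k | CNY | ASSUMED |
| annual care mRS 0–1 / 2–5 | 8,000 / 40,000 | CNY/y | ASSUMED |
| recurrent-stroke / sICH event | 30,000 / 20,000 | CNY | ASSUMED |
| alteplase | 2,550 = mean(1,700, 3,400) | CNY | 20 mg / 50 mg procurement prices are the OWSA bounds |
| discount rate | 0.05 (0–0.08) | 1/y | |
| WTP thresholds | 95,749 / 287,247 | CNY/QALY | 1× / 3× per-capita GDP |

All costs are 2024 CNY; the package performs no inflation or currency
conversion. `ASSUMED` defaults stand in for literature inputs whose
values are not printed in the source material; they are flagged in the
packaged YAML and fully overridable. Ranges for parameters without
printed intervals were fixed once as symmetric relative bands (utilities
±10 % clipped to [0,1]; care/event costs ±25 %; recurrence rates ±50 %;
case fatality ±25 %; recurrence utility and sICH disutility ±20 %).

Under these assumed care costs the base case comes out *dominant*
(alteplase saves lifetime cost while gaining QALYs): the care-cost gap
between dependent (mRS 2–5) and independent (mRS 0–1) states outweighs
the drug and sICH costs. Published analyses with proprietary cost inputs
place the same comparison in the first quadrant at a small positive
ICER; either way the conclusion — highly cost-effective against a 1×
per-capita-GDP threshold — is identical, and the QALY gain is determined
by the printed trial outcome distributions, not the assumed costs.

## Sensitivity analysis

**One-way (tornado).** Every parameter with a non-degenerate range is
set to each bound with all else at base case. A component of an mRS
distribution is swept by fixing it at its bound and rescaling the other
six proportionally so the simplex constraint holds; bounds that would
leave [0,1] are clipped with a warning. Entries are sorted by
`|ICER(high) − ICER(low)|`. Re-evaluating any swept parameter at its
point estimate reproduces the base-case ICER to 1e-9 relative tolerance
(regression-tested).

**Probabilistic.** Each draw samples all uncertain parameters
independently: each arm's mRS block from a Dirichlet with concentration
equal to the source-trial arm scale (115) — a deliberate multivariate
replacement for per-component betas, which would break the sum-to-1
constraint; scalar probabilities and utilities from betas; costs from
gammas. Beta and gamma shapes are moment-matched with SD =
(high − low)/3.92, treating printed ranges as symmetric Wald-style 95 %
intervals; the fitted mean is exact and a variance reaching the
Bernoulli bound is clamped just below it. Zero-width ranges yield
degenerate (fixed) samplers. Sampled alive-state utilities are re-sorted
descending so monotonicity in disability is preserved. Death hazard
ratios, the discount rate and structural probabilities are declared
`fixed` and not sampled (hazard ratios fit neither the beta nor the
cost-gamma family; their influence is captured in the tornado).
Default 1,000 iterations (an analyst-chosen default; the seed is
recorded in the output), CEAC grid 0–120,000 CNY/QALY in 1,000-CNY
steps, with acceptability = fraction of draws with positive incremental
net monetary benefit. The CEAC crossing of 0.5 is linearly interpolated;
with the packaged defaults the curve starts above 0.5 at WTP = 0
(consistent with dominance), so the crossing is reported at the grid
boundary with a flag rather than asserted.

## Synthetic data and validation

The generator treats a model spec as ground truth and emulates a
two-arm trial: multinomial mRS counts per arm (default 115 patients per
arm, matching the granularity of the source proportions, e.g.
0.0087 ≈ 1/115), binomial sICH counts, Wald 95 % ranges for the observed
proportions, gamma cost noise (CV 0.2) and beta utility noise anchored
at the point estimates. Drug procurement prices, recurrence dynamics,
hazard ratios and the life table are administrative/structural inputs
and pass through unchanged. `noise_scale=0` returns the truth exactly.
What the generator does *not* emulate: patient-level covariates,
time-to-treatment strata, correlated cost/utility errors, or
non-multinomial outcome misclassification — so passing recovery tests
demonstrate correct propagation of idealised trial sampling noise, not
robustness to real-world data pathologies.

The microsimulation oracle replays the exact cohort event probabilities
and payoff rules for individual seeded trajectories (including the
half-cycle payoff convention, applied per transition as
`½(payoff_start + payoff_end)`); cohort totals agree with its means
within 3 Monte-Carlo SE at 2×10^5 individuals across randomized
parameter bundles (tested). The recovery experiment (200 replicates of
115-patient arms) checks that the truth-run ICER lies inside the
replicate 2.5–97.5 percentile band and that the mean QALY-difference
bias is within Monte-Carlo error.

## Numerical choices and degenerate inputs

- Occupancy is validated to sum to 1 within 1e-9 every cycle; an input
  mRS vector is renormalised when its sum is within 1e-3 of 1 (printed
  proportions carry rounding) and rejected beyond that.
- `annual_prob_to_cycle(1, ·)` returns 1 (documented limit);
  probability 0 returns 0 exactly.
- ICER is undefined at ΔE = 0 (classification falls back to the cost
  sign). Threshold ties go to the less favourable adjacent band
  (ICER = 1× GDP → "cost-effective"). Dominant pairs classify as
  "highly cost-effective" irrespective of thresholds; the cheaper-but-
  less-effective (south-west) quadrant is labelled on its own and never
  auto-classified.
- Strict validation (monotone utilities/hazard ratios/recurrence rates,
  drug base price = mean of unit prices) applies when loading a spec
  file; OWSA/PSA perturbation rebuilds relax exactly those monotone
  constraints so printed sweep bounds (e.g. the mRS 2 hazard-ratio low
  bound 0.89) remain representable.
- Problem sizes in the shipped tests and examples — 2×10^5-patient
  microsimulations, 200-replicate recovery runs, a few hundred PSA
  draws — were chosen to keep Monte-Carlo error well below the asserted
  tolerances while remaining quick on a laptop.

## Known limitations

- No tunnel states: recurrence history is not tracked, so a patient's
  second recurrence carries the same risk as the first.
- A uniform case-fatality and a one-state worsening rule compress what
  is surely an mRS-dependent recurrence severity distribution.
- The ΔC sign (and hence the dominance finding, the PSA quadrant and
  the CEAC crossing point) hinges on the `ASSUMED` care-cost defaults;
  analyses with jurisdiction-specific costs should override them.
- Parameters are sampled independently in the PSA (no correlation
  structure between, e.g., costs and utilities).
- No EVPI/EVSI, no more-than-two-strategy frontier, no time-to-treatment
  stratification.
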