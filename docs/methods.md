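# Methods

## Model structure

The model is a quarterly-cycle Markov state-transition simulation over a
10-year horizon (40 cycles), comparing three strategies for symptomatic
meniscal tear with knee OA:

* **PT** — physical therapy alone;
* **DelayedAPM** — PT first; every subject still in moderate pain at three
  months undergoes arthroscopic partial meniscectomy (probability 1, one
  gate, no later crossovers);
* **ImmediateAPM** — surgery as first-line treatment.

States combine pain (low/moderate, KOOS dichotomised at 25), KL grade
(0/1, 2, 3, 4), TKA status with quarters since surgery, and a
consecutive-moderate-pain counter.  Everyone enters alive, symptomatic
(moderate pain), KL distributed 44.8 / 26.4 / 28.8 / 0 %, age
Normal(58, 7) truncated to [45, 75].

**Pain dynamics** are treatment-attributable for the first six months only:
a failed-pain-relief draw governs months 0–3, stratum-specific incidence
and resolution govern months 3–6, both stratified by treatment context
(APM, APM-after-PT, PT) and KL band (0–2 vs 3–4).  Crossover surgery in the
delayed strategy has a single failed-relief window in the quarter after the
procedure (its months 3–6 rows are zero).  From month 6 onward pain
incidence and resolution are OA-driven, by KL grade, independent of the
original treatment.  The 6-month moderate-pain fractions this induces
(PT ≈ 61 %, both APM strategies ≈ 38 %) are emergent, not imposed.

**Structural progression**: KL 0/1 knees develop radiographic OA at the
age-specific annual incidence; KL 2→3 and 3→4 progress at 0.0735 and 0.0267
per year, at most one grade step per quarter; KL 4 is absorbing.  A
progression multiplier (default 1 — surgery assumed not to alter structural
progression) applies to knees that underwent APM, exposed for two-way
sensitivity analysis.

**Knee replacement**: subjects with KL 3/4 and moderate pain in at least
two consecutive quarters after the initial treatment period elect TKA at
the age-specific annual utilisation rate (0.064 / 0.119 / 0.030).  TKA is
once per subject; post-TKA pain is low with probability 0.862 per quarter
during the first post-operative year and 0.960 thereafter (the "annual
efficacy" figures interpreted as per-quarter state probabilities — the
alternative, attain-then-maintain reading is not distinguishable from the
published aggregates).

**Death** can occur in any state at the all-cause rate of a bundled life
table, plus perioperative mortality (APM 1.5 % complications × 1.1 % case
fatality; TKA 3.6 % × 0.6 %) and pharmacologic adverse events
(11.1 %/year of moderate-pain management, case fatality 0.5 %).  The
packaged life table is a **synthetic Gompertz approximation** to the pooled
2009 US all-cause table (q(x) = 3.116·10⁻⁵·e^{0.095x}, capped at 1 from age
110); any CSV with columns `age,annual_death_prob` can be substituted.

## Accrual conventions

* Annual probabilities convert to quarterly as 1 − (1 − p)^¼ (constant
  hazard within the year).
* Event order in a cycle: death → KL progression → treatment/TKA election →
  pain update → accrual.  Utilities and recurring costs accrue on the state
  occupied during the quarter (post-update); procedure bundles accrue in the
  surgery quarter.  No half-cycle correction: with three-month cycles the
  correction is below every tolerance used here.
* Discounting: (1.03)^(−q/4) with the first quarter undiscounted; QALYs and
  costs both at 3 %/yr.
* Treatment costs (2013 USD): the immediate-APM bundle charges procedure
  ($2,867) + post-operative healthcare ($454) + rehabilitation ($439) +
  expected complication (1.5 % × $11,589).  PT strategies charge healthcare
  ($209) + rehabilitation ($568) in quarter 1.  Crossover surgery charges
  procedure + post-operative healthcare + expected complication but **no
  second rehabilitation course** — PT costs apply only to cycles in which PT
  was used, and the crossover subject's course was already charged; this
  convention also reproduces the published incremental costs to within a
  few dollars, where double-charging overstates them by ~25 %.
  Pain-management costs ($276 moderate / $99 low per quarter, plus expected
  pharmacologic-complication cost) accrue every quarter including post-TKA;
  TKA charges $20,282 + 3.6 % × $15,149.
* Time costs: hours lost × $22.33/h.  Months 0–6 hours (109 surgery, 79 PT;
  87/42 by pain in months 3–6) are used as published, which already average
  over employed and unemployed subjects; hours after month 6 (70/30 per
  quarter by pain) are weighted by an employment-probability schedule.  The
  default schedule is **constant 0.60** — the trial cohort's employment
  rate, and the only employment figure the main text provides; an
  age-declining schedule can be supplied as interpolation breakpoints but
  materially underpredicts the published 10-year time-cost aggregates.
  Time costs are accrued in parallel with direct costs, so a single run
  serves both the payer and the societal perspective.

## Evaluation modes

**Cohort mode** (default) propagates the exact state-occupancy distribution
— entry-age integer-year bins (truncated-normal weights, bin-midpoint ages)
× KL × pain × TKA-counter × consecutive-pain-counter — so results are
deterministic given a parameter set; occupancy (alive + dead) is conserved
to < 10⁻¹⁰ every quarter.  One-year age bins rather than coarser bands keep
the discretisation bias below the Monte-Carlo resolution of the
microsimulation comparison.  **Microsimulation mode** draws individual
subjects (continuous ages, Bernoulli transitions, realised adverse events)
with the same transition rules; at n = 50,000 it agrees with cohort mode
within Monte-Carlo error and provides distributional output.

## Parameters and uncertainty

The base case uses the published point estimates.  The PSA samples exactly
the parameters that carry distributions in the source table: 14 beta
specifications (treatment-window pain probabilities, parameterised by
stratum event counts) and 12 gamma specifications (six cost rows, six
hours rows), all independent.  Four gamma rows have printed means that
disagree with alpha/lambda by 5–8 % ($209, $276, 79 h, 87 h); both are
retained — base case uses the printed mean, PSA draws use (alpha, lambda) —
and loading warns about the mismatch.  Utilities, procedure costs,
progression, uptake, TKA efficacy and adverse-event rates are fixed in the
PSA.  Draws are reproducible: iteration *i* of master seed *s* uses the
deterministic child seed (s, i), so any single iteration can be replayed.

EVPI is mean-of-max minus max-of-mean over the NMB matrix.  EVPPI uses
nested two-level Monte Carlo (outer draws fix the named group, inner draws
integrate the complement; floored at zero), which is estimator-assumption
free; the estimator is validated against a closed-form two-strategy
Gaussian decision problem.  Named groups: `delayed_apm_efficacy`,
`apm_progression` (structurally zero — those rates carry no distribution),
`pain_management_costs`, `time_costs`.  Population VOI multiplies
per-person EVPI by 352,000 persons/year over a 3-year usable life of
information, discounting successive annual cohorts at 3 %.

## Synthetic trial generator

`generate_trial` emulates the individual-level structure the estimation
assumes: per-arm KL bands from the cohort shares, Bernoulli 3- and 6-month
pain outcomes at the stratum probabilities (the crossover arm applies PT
quarter-1 probabilities, then the post-crossover failed-relief draw to
subjects still in pain), gamma-distributed per-subject costs and hours, and
Bernoulli(0.60) employment.  It does **not** emulate longitudinal follow-up
beyond six months, within-subject cost correlation, measurement error in
KOOS, or loss to follow-up — parameter-recovery tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness to
real-world data pathologies.  `estimate_from_trial` recovers beta counts per
stratum and method-of-moments gamma fits (α = mean²/var, λ = mean/var),
flagging empty or zero-variance strata as unestimable.

## Numerical and design choices

* Frontier construction sorts by cost (ties broken by descending QALYs, the
  second of two identical strategies being weakly dominated), removes
  strong dominance, then iteratively removes extended dominance until
  adjacent ICERs increase strictly; verified against a brute-force
  convex-frontier oracle on 1,000 random instances.
* CEAC ties (zero-probability for continuous draws) split equally; the WTP
  grid is $0–150,000 in $1,000 steps.
* The consecutive-pain counter is capped at 2 (the election gate) and the
  post-TKA counter at 5 quarters (first-year vs subsequent efficacy), which
  are sufficient statistics for every downstream rule.
* Problem sizes: acceptance-grade runs use the cohort expectation for point
  estimates and 10,000 PSA iterations (about a minute on one core);
  microsimulation validation uses 50,000 subjects; parameter recovery uses
  100,000 subjects per arm.

## Known limitations

* The published supplement (exact employment-adjustment tables, parameter
  histograms, two-way sensitivity surfaces) is not part of the inputs; the
  employment schedule and the crossover costing convention are this
  package's own documented choices, calibrated only against figures printed
  in the main text.
* The QALY difference between Immediate and Delayed APM is ~0.007 here; the
  published ICER arithmetic implies ~0.0097.  Because the two strategies
  differ only in the first two quarters (both show ~38 % moderate pain at
  six months), ratios built on this difference — notably the
  Immediate-vs-Delayed ICER under the societal perspective — are the least
  reproducible outputs and can differ from the published values by tens of
  percent while absolute costs, QALYs and trajectories agree closely.
* No KL-4-at-entry subjects, no subjects under 45, no revision TKA, no
  sex-specific mortality or employment, and no correlation between PSA
  parameters (none is published).
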