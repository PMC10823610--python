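# Methods

## Model structure

The analysis chains a short-term decision tree to a long-term Markov cohort
model over seven health states defined by the modified Rankin Scale
(mRS 0–5 alive, mRS 6 dead).

**Decision tree (randomization → day 90).** Patients enter at age 60 with
baseline mRS 0–1 (90.3 % / 9.7 %) and receive either EDB (¥33/unit ×
6 units/day × 14 days = ¥2,772) or HUK (¥100/unit × 1 unit/day × 21 days =
¥2,100). The tree's endpoint is the arm's day-90 mRS distribution — for the
EDB arm the MAIC-adjusted distribution, for HUK the aggregate trial
distribution. Storing the drug cost as unit price × units/day lets the
one-way sensitivity analysis on unit price scale the whole course cost.

**Markov model (day 90 → 40 years).** The day-90 distribution is held for
the whole first model year ("cycle 0"): the 90-day tree window is filled up
to one year, and no extra transitions are invented inside it. Cycles are
annual; the cohort is propagated by per-cycle 7×7 row-stochastic matrices
for 40 transitions. Within a transition the event order is: death first,
recurrence conditional on survival, redistribution conditional on
recurrence. For alive state *s* in Markov year *k* (age 60 + k − 1):

* mortality `p_d(s) = 1 − (1 − q_age)^HR(s)`, where `q_age` is the
  national life-table annual probability (band lookup; 90+ uses the open
  band) and `HR(s)` the state-specific mortality hazard ratio. Applying
  the hazard ratio on the rate scale keeps probabilities inside (0, 1);
  the naive product `q·HR` exceeds 1 for mRS ≥ 5 past age 90. The naive
  (capped) product is available as `hr_mode="probability"` for convention
  calibration; it changes lifetime QALYs by < 0.5 %.
* recurrence `r_k` by years since the index stroke (5.9 % in year 1
  declining to 1.6 % from year 10), identical across states and arms.
  Surviving recurrences move to an equal-or-worse state via the
  redistribution matrix; its columns sum to 0.8217 and the remainder,
  17.83 %, is treated as recurrence case fatality added to that cycle's
  death flow. Time-since-recurrence tunnel states are out of scope; the
  recurrence clock runs from the index stroke for everyone.

## Accrual conventions

* **Half-cycle correction**: trapezoid weights on state-membership accruals
  (QALYs, stroke-year secondary-prevention costs): ½ at cycle 0 and the
  final cycle, 1 elsewhere. One-time event costs (drug course,
  per-event hospitalization) are charged in full in the event cycle.
* **Discounting**: cycle *k* accruals × (1 + r)^(−k), cycle 0 undiscounted;
  5 %/year for costs and outcomes (each 0–8 % in the DSA).
* **QALYs**: Σ_s occ(k, s)·u(s) per cycle, minus the 0.086 stroke-year
  disutility charged once at the index year (day-90 survivors) and once per
  recurrence year (recurrence survivors).
* **Costs** (2021 ¥): one-time hospitalization per stroke event by mRS
  group (0–2: 12,614; 3–5: 17,223; recurrence deaths: 13,951 at the death
  tariff), charged at the index event (cycle 0) and at every recurrence by
  post-recurrence group; plus the annual secondary-prevention cost
  (0–2: 9,264; 3–5: 14,238) charged in stroke years only — cycle 0 for all
  day-90 survivors (half-cycle weighted) and each recurrence year for the
  recurrence survivors. Charging it instead to every alive patient every
  year would multiply the component roughly fifteen-fold and is
  irreconcilable with the published cost breakdown, so the stroke-year
  reading is used. The recorded mean hospital stay (9.9 days) is carried in
  the configuration but no formula consumes it.

## MAIC stage

Unanchored MAIC with 13 matching covariates. Mean and proportion targets
enter the design matrix as `x − target`; median targets as
`I[x ≤ target] − ½`, so the weighted share at or below the target median is
one half (first-moment matching cannot hit a median directly; variance
matching is not attempted). Weights solve the convex program
min_b Σ exp(z_i·b) by damped Newton with analytic gradient and Hessian
(max 500 iterations, gradient tolerance 1e-10, BFGS fallback on a singular
Hessian); separation — an unattainable moment — is reported as a diverging
coefficient norm. Weights are rescaled to mean 1; all weighted statistics
are scale-invariant. Diagnostics: per-covariate balance gaps and the Kish
effective sample size (Σw)²/Σw². Missing covariate values are rejected
(complete-case tables only).

## Synthetic IPD generator

Emulates the EDB trial arm (n = 1,200) for end-to-end MAIC rehearsal. Only
medians and proportions of the baseline table are published, so the
families are package choices: truncated normals for age (median 62.96,
SD 9) and BMI (24.20, SD 3); onset-to-treatment time as 48 h × Beta(2.66,
2.0) (median ≈ 28 h, respecting the 48 h eligibility window); NIHSS as
6 + (Geometric(½) − 1) capped at 25 (median 6, eligibility 6–25);
independent coin flips for the eight binary covariates at the published
proportions, with a mild age link on coronary heart disease (+0.04 logits
per year). Day-90 outcomes come from a proportional-odds model whose
cutpoints are calibrated to the published pre-adjustment outcome margins by
a deterministic root-finder on the realized covariate sample; latent slopes
0.35/NIHSS point, 0.30/decade of age and 0.40 for diabetes make outcomes
covariate-dependent so that reweighting toward the comparator's (sicker)
baseline visibly worsens the weighted mRS distribution. The generator is
deterministic given its seed. It does not emulate dropout, missingness,
site effects, or within-trial covariate correlations beyond the age–CHD
link — so passing tests show the pipeline's correctness on trial-*like*
data, not distributional fidelity to the real trial.

Because the comparator trial reports 92.06 % baseline mRS 0–1 against
99.83 % in the IPD, the weights concentrate on the few mRS>1 patients and
the effective sample size drops to a few hundred of 1,200 — an inherent
feature of unanchored MAIC with a near-degenerate matching covariate, and
the reason a fixed generator seed is used where exact moment matching is
asserted.

## Sensitivity analyses

* **DSA**: 22 one-way ranges (drug unit prices, costs, utilities,
  disutility, hazard ratios, both discount rates). Each side reruns both
  arms; output sorted by |ICER_high − ICER_low|.
* **PSA**: 1,000 second-order iterations by default. Gamma (shape–scale)
  for costs, beta for utilities and the disutility, lognormal (log-mean,
  log-sd) for hazard ratios; every configured pair reproduces its base
  value (mean, or median for lognormal) within 1 %. Parameters are drawn
  independently — no correlation structure is published — and utilities are
  not re-sorted after drawing, so monotonicity across mRS may transiently
  break in a draw. Each iteration shares one draw across both arms; the
  arms differ only in day-90 distribution and drug cost, so parameter
  uncertainty creates no spurious arm differences. Day-90 distributions and
  drug prices carry no published distribution and are excluded from the
  PSA (drug prices are DSA-only). The RNG is a seeded generator with
  iteration-indexed substreams; results are bit-reproducible given the
  seed. The acceptability curve uses a 0–3× threshold grid in ¥1,000 steps
  (the grid itself is a package choice).

## Numerical choices

Internal arithmetic is double precision throughout; rounding only at the
reporting layer (QALYs to 3 dp, ¥ to integers) — comparative statistics are
computed from unrounded arm outcomes. Transition-matrix rows and trace rows
are asserted to sum to 1 within 1e-9. Zero incremental QALYs yields an
explicit "undefined" ICER flag; the dominant/dominated quadrants are
flagged rather than reported as negative ratios. The deterministic cohort
trace is cross-checked in the test suite against a 200,000-walker
individual-level microsimulation through the same matrices (three seeds,
maximum occupancy gap < 0.005); the microsimulation is a test oracle, not a
production mode.

## Reproduction accuracy and known limitations

With the packaged inputs the pipeline yields EDB 7.667 / HUK 7.537
discounted QALYs, ¥28,447 / ¥27,628 discounted costs, ΔQALY 0.130,
Δcost ¥819, ICER ¥6,315/QALY, and 99.6 % cumulative mortality at cycle 40.
The published analysis reports 7.621 / 7.468 QALYs, ¥28,687 / ¥27,832,
ΔQALY 0.153, Δcost ¥856, ICER ¥5,608, mortality > 99.7 %. Per-arm levels
and cost components agree to ≈ 1 %, but the incremental QALY gap is a
difference of two much larger opposing terms, which amplifies small
structural discrepancies: the three published ICER values across the mRS2
utility range are exactly collinear in ΔQALY(u₂) and imply an internal
ΔQALY of 0.1527 with sensitivity −0.550 per unit u₂, whereas this
implementation (and every documented convention variant: hazard-ratio
scale, life-table interpolation, event ordering, age offset, recurrence
fatality vs stay-in-state readings) produces 0.127–0.136 and −0.54…−0.57.
Rounding of the published day-90 distributions (0.1 % precision) can move
ΔQALY by at most ±0.006. Reproducing 0.1527 would require roughly one
extra percentage point of annual exit from states mRS 2–5 beyond what the
published mortality and recurrence inputs generate; no stated model
element supplies it. Consequently the quantities that divide by the
incremental QALYs inherit the gap — most visibly the ICER at the upper
mRS2 utility bound (≈ ¥38,000 here vs ¥17,769 published), where the
denominator nearly vanishes. Directional conclusions (cost-effectiveness
at the threshold, tornado ordering, 100 % acceptability) are insensitive
to this and reproduce exactly.

Other limitations: no indirect/societal or adverse-event costs (excluded
by design); recurrence risk independent of mRS state; no treatment effect
beyond the day-90 distribution; two-arm comparison only (no efficiency
frontier).
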