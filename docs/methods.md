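# Methods

## Cohort model

The disease course is a discrete-time Markov chain over four health states
— controlled RRMS (entry-only), relapse, remission, death — expanded by
treatment arm (teriflunomide vs switched-to second-line DMT) into six
compartments; (controlled, switched) cannot occur because switching happens
out of relapse and remission never returns patients to the controlled
state. Cohorts of 1000 patients are propagated as expectations (no
microsimulation) through 7 annual cycles.

Within-cycle flow order in the relapse compartment: death first, then
remission (probability 0.20 of survivors), then — naïve strategy, cycles
≥ 2 only — switching (0.10 of survivors who did not remit); the remainder
stays in relapse on its current arm. This order is a modelling choice the
source setting does not pin down; it is the one that produces coexisting
on-drug and switched relapse/remission compartments, matching the
published occupancy layout. Remission is not sticky: remitted patients
face the same annual relapse probability as controlled patients, on their
current arm. Switched patients reuse the teriflunomide-arm transition
probabilities, as no DMT-specific efficacy is available.

Mortality uses an (age, sex)-keyed annual probability table with no
extrapolation; the cohort is modelled at its mean entry age (33 naïve,
37 experienced) advancing one integer year per cycle, and the sex mix
enters as a fixed female share (0.7871 / 0.7708) blending the sex-specific
rates.

**Half-cycle correction.** Deaths are assumed to occur mid-cycle:
survivors earn a full cycle of person-time in their end-of-cycle
compartment, decedents half a cycle in the compartment they died from.
The same accrual weights drive costs, LYS and QALYs uniformly.

**Discounting.** Cycle-*t* accruals are discounted by (1+r)^−(t−1) with
r = 3%: the first cycle is undiscounted, as are one-off entry
assessments. This timing is forced by the published life-year totals
(6.406/6.402 discounted LYS over 7 years is only attainable when the
first cycle carries no discount: Σ_{t=0..6} 1.03^−t = 6.4172, whereas
Σ_{t=1..7} 1.03^−t = 6.2303). `discount_total` accepts explicit exponent
vectors for other conventions.

## Valuation

Cost items attach to compartment stocks (per person-cycle), to event
flows (new relapses, new remissions, switches — per episode), or to model
entry (once, undiscounted). Administration tariffs that would
double-count a separately priced drug are halved. Time losses are valued
at the gross hourly wage for working-age patients (< 70 years), the
take-home wage for older patients' and all caregivers' leisure time, and
the home-helper gross wage for housekeeping patients. The
healthcare-sector perspective counts block A only; the societal
perspective A + B + C. Per-patient figures divide by the 1000 starters,
not by survivors. All arithmetic is full precision; euros are rounded
only at the reporting layer.

**Adherence mechanism.** The base case assumes 100% adherence. In the
adherence scenario, non-adherent person-time accrues no teriflunomide
acquisition cost and loses the treatment effect: the effective relapse
probability is a·p + (1−a)·min(1, p/m) with treatment-effect multiplier
m = 0.7 (configurable). The mechanism is a package design choice; only
the adherence grid, not the mechanism, is given by the setting modelled.

## Parameter distributions

Distributed parameters are fitted by the method of moments: beta for
dichotomous probabilities and utilities, gamma (shape = m²/se²,
scale = se²/m) for resource volumes and EDSS scores, normal for non-drug
unit costs (draws truncated at zero by resampling, counted), Dirichlet
(α_i = share_i × precision, default precision 100) for the switch split
across five DMTs. Dispersion comes from a standard error or a coefficient
of variation (se = |m|·cv); defaults when the registry is silent are
cv = 0.2 for volumes/EDSS and cv = 0.1 for unit costs. 95% intervals are
the 2.5th/97.5th percentiles of the fitted distribution, or the stated
range for fixed parameters.

## Sensitivity analyses

*One-way*: every eligible parameter is set to its 95% CI or range limits
(clamped to its support and flagged if infeasible), the model re-solved,
and the signed percentage departure recorded as
100·(ICUR_s − ICUR_base)/|ICUR_base| — signed ICURs keep a dominant
(negative) base case meaningful, and dominance flips are flagged
separately. Drug prices, posology and administration counts are excluded
by convention; the discount rate participates as a fixed parameter with
range (0, 0.05). Dirichlet shares are renormalised after replacement.

*Scenarios*: ICUR at each truncated horizon 1..7; adherence lowered over
a grid (0.9 … 0.4 — the grid deliberately includes 0.4 because the
published narrative reports results at 40% although the scenario is
described as 90–50%); remission probability raised over 0.3 … 0.9, both
applied to both cohorts symmetrically.

*PSA*: per iteration one joint draw of all 438 distributed parameters —
parameters shared between cohorts (unit costs, wages) are drawn once, so
spurious ΔC variance is avoided — applied to both strategies, fixed
parameters at base case. Infeasible draws (e.g. a wage ordering
violation) are resampled and counted; the resample fraction stays below
1%. CEAC(s, λ) is the fraction of iterations where s has the strictly
highest NMB (ties to the comparator, counted); CEAF reports, at each λ,
the strategy with the highest expected NMB together with its CEAC value.
The default willingness-to-pay grid is 1000 points from €0 to €99,900
(€100 steps), configurable.

## Synthetic registry

The generator emulates the structure of the full 721-parameter registry
(438 distributed / 283 fixed): ~85 structural parameters carry the
printed settings exactly (remission 0.20, switch 0.10 from cycle 2,
adherence 1.0, discount 3%, ages, female shares, the five switch DMTs),
and the count is padded with small "micro" resource items (gamma volume +
normal unit cost pairs, and fixed posology-like items with OWSA ranges)
attached to real compartments, so every registry row flows through the
model. Relapse risk is logistic in a gamma-distributed EDSS score
(means 2.0 naïve / 3.0 experienced mapping to annual probabilities
≈ 0.305/0.325), calibrated once so the mean controlled-state occupancy
(~29%/28% of the cohort) and the strong-dominance base case match the
published structure. Mortality is a Gompertz-like synthetic table
(ages 25–60, constant sex ratio, anchored at Italian adult magnitudes).
Utility and cost levels were set once so that QALY/LYS ratios (~0.57 and
~0.49) and cost-category shares (A ≈ 80–85%, B ≈ 10–15%, C ≈ 6%)
approximate the published base case; this is a structural emulation, not
a value-by-value reproduction, and quantities that depend on the exact
supplementary values (tornado ranking, CEAC intercepts, the yearly-ICUR
profile — which is dominant at every horizon here rather than peaking
mid-horizon) are not reproduction claims. What passing tests show is that
the *machinery* (conservation, half-cycle accounting, discounting,
distribution fitting, decision rules) is correct; they do not validate
the synthetic values against real data.

## Numerical choices and problem sizes

Conservation is enforced to 1e-9 per cycle; transition rows to 1e-12.
Ties in NMB comparisons go to the comparator. OWSA solves ~570 parameter
variations in seconds; the PSA runs 10,000 iterations in about two
minutes on one CPU (tests use 40–300 iterations; the acceptance script
uses the full 10,000). Property tests use derandomised hypothesis sweeps;
Monte-Carlo assertions use 3-standard-error tolerances at the stated
sample sizes.

## Known limitations

* Cohort expectations only; no individual heterogeneity in age, sex or
  EDSS beyond the fixed mixes.
* No RRMS→SPMS conversion (teriflunomide has no SPMS indication, which
  also motivates the 7-year horizon).
* Switched-arm dynamics reuse teriflunomide-arm probabilities.
* The synthetic registry is a stand-in: absolute cost levels and PSA
  probabilities depend on its calibration, not on transcribed source
  values.
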