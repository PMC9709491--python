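# Methods

## Scope and model overview

`dupsim` implements an early health-economic evaluation of intranodular
adalimumab for progressive early-stage Dupuytren's disease (DD) from a UK
NHS/PSS perspective, in two parts:

1. a **within-trial cost-utility analysis** over 12 months: EQ-5D utilities
   collected at 0/3/6/9/12 months are converted to QALYs by trapezoidal
   area-under-curve; arm differences in QALYs and costs are estimated by
   covariate-adjusted OLS and bootstrapped;
2. a **patient-level simulation** ("microsimulation with Markov-like
   structure") extrapolating 18-month trial outcomes over a lifetime, with
   probabilistic sensitivity analysis (PSA), cost-effectiveness
   acceptability curves (CEAC), and expected value of (partial) perfect
   information (EVPI/EVPPI).

Because the underlying trial's individual-patient data are not public, both
parts run on synthetic data generated by the package itself; all population
parameters are published summary estimates or documented assumptions.

## Disease model

Time runs in 6-month cycles from randomization to a 55-year horizon.  The
trial period covers 0–1.5 years; the simulation proper starts at trial end.

**18-month outcome.**  Each patient is assigned one of three outcomes with
arm-specific probabilities (standard care: late-stage 0.2149, quiescent
0.2209; adalimumab: 0.1800, 0.3696).  A single uniform deviate per patient is
shared across strategies (common random numbers), mapped as: late-stage if
`u < p_late`, quiescent if `u >= 1 − p_quiescent`, progressive otherwise.
This makes each category monotone in its own probability, so a patient
quiescent under standard care is quiescent under adalimumab too.

**Progressive disease.**  Flexion deformity (FD) follows a Gaussian random
walk floored at 0°.  The published 18-month regression (constant 0.8631°,
ectopic-disease coefficient +8.5189°, residual RMSE 12.6079°) is scaled to
6-month increments as mean/3 and SD/√3, so three independent increments
reproduce the 18-month mean and RMSE exactly.  At model start, progressive
patients advance by one 18-month draw truncated into [0°, 30°] (they are, by
assignment, not yet late-stage).  Crossing FD > 30° is permanent
(late-stage).  Walk shocks are indexed by *progression age* (cycles since
the walk began) rather than calendar time, so that under common random
numbers a longer quiescence shifts — never shortens — time to late stage.

**Quiescence.**  Quiescent patients hold FD fixed for `quiescence_duration`
(base 3 years; 1.5–5 in sensitivity analyses) from trial end.  When it ends:
under standard care or a single course, the patient becomes progressive;
under the retreatment strategy a new course (4 × £475) is given in that same
cycle and quiescence continues indefinitely.

**Late stage.**  Eligible patients (untreated, or relapsed/failed) elect
surgery with a per-cycle probability.  The sequence is: percutaneous needle
fasciotomy (PNF) up to three times, repeated only after an *initially
successful* PNF (post-operative FD ≤ 5°) relapses; any PNF failure switches
the pathway to limited fasciectomy (at most one); a relapsed fasciectomy can
be followed by one dermofasciectomy; then best supportive care.  Successful
procedures relapse with per-cycle probabilities; relapse returns the patient
to the untreated late-stage state.

**Mortality.**  Death can occur from any state with probability
`1 − exp(−HR·h(age)·0.5)` per cycle, where `h` is a life-table annual hazard
and HR an excess-mortality hazard ratio for DD (1.27), independent of stage
and strategy — so life-years are strategy-invariant under common random
numbers.  The packaged life table is a two-parameter Gompertz,
`h(age) = 1.253e−5 · exp(0.1015 · age)` (unisex), chosen so that the default
cohort's life expectancy from randomization is 22.6 years; it implies a
general-population annual hazard of ≈0.006 at age 61, plausible for UK
adults.  A user CSV (age, sex, hazard) overrides it; ages beyond the table
maximum die within the cycle.

## Economics

* **Utilities.**  Annualized EQ-5D utility in early states is
  `0.3847 + 0.5410 × baseline utility`, plus 0.0395 while quiescent; late
  states subtract a state-specific decrement; capped at 1.
* **Costs.**  Only interventions are costed in the model period (courses,
  procedures plus an outpatient/physiotherapy add-on).  One course is
  `4 × £475`.  Prices are 2018–19 GBP.
* **Discounting.**  3.5% per annum beyond the 18-month trial period; the
  trial period itself is undiscounted.
* **Trial period.**  Trial-window QALYs use the same utility regression
  (quiescence gain accrued over the 6–18-month window the regression
  covers); trial costs are a fixed £307 non-intervention background plus one
  course for the adalimumab strategies.  Lifetime totals are trial + model.
* **Accounting convention.**  "Years free of late-stage DD" is an
  effectiveness measure and is discounted like QALYs; "years with
  early-stage DD" is an undiscounted occupancy time.  A patient alive at
  cycle start accrues the full cycle's cost and utility, then survival to
  the next cycle is tested (no half-cycle correction).
* **Incremental analysis.**  Strategies are sorted by mean cost; strict
  dominance, then extended dominance are flagged so that frontier ICERs
  increase strictly.  Pairwise ICERs vs standard care are reported alongside
  (the headline convention).  A zero QALY difference flags the ICER
  undefined rather than dividing.

## Probabilistic sensitivity analysis

Each uncertain input carries a 95% interval in the configuration and is
sampled as follows (the source analysis used bootstrap replicates that are
not available, so parametric families are moment-matched to the published
intervals):

| input group | family | calibration |
|---|---|---|
| 18-month outcome probabilities (per arm) | Dirichlet over (late, quiescent, progressive) | concentration = mean of the two implied Beta concentrations from the interval widths; guarantees `p_late + p_quiescent ≤ 1` per draw |
| regression coefficients, quiescence utility gain | Normal | SD = (upper − lower)/3.92 |
| FD residual RMSE | fixed | no interval published |
| quiescence duration | Uniform(1.5, 5) years | stated sensitivity range |
| late-stage probabilities / utility decrements | Beta | moment-matched |
| procedure costs | Gamma | moment-matched |
| mortality hazard ratio | log-Normal | interval on the log scale |

Sampling, cohort generation and simulation use independent streams derived
from one master seed (`numpy` SeedSequence spawning); identical inputs give
bit-identical results.  Within a draw every patient is simulated `n_reps`
times per strategy with common random numbers (the same outcome deviate and
cycle-level shocks across strategies), which removes between-strategy Monte
Carlo noise from incremental quantities.

Default run sizes are 1,000 draws × 100 repetitions (`scale="paper"`); the
package's own test suite and the reproduction checks use 200 × 20
(`scale="desk"`, a few tens of seconds on one CPU), which is sufficient for
the means and CEAC probabilities checked there.

**CEAC**: per willingness-to-pay λ, the fraction of draws in which each
strategy maximizes net benefit λ·QALYs − cost; floating-point ties (measure
zero) are credited to the strategy with the lower mean cost.  **EVPI** per
patient is `E[max NB] − max E[NB]`; population EVPI is a bare product with
the 2,584,411 UK prevalent cases (no incidence stream or population
discounting).  **EVPPI** uses a single-loop regression estimator: each
strategy's NB is regressed on an additive cubic B-spline basis of the
subset's sampled values (dummy encoding for near-discrete parameters) and
the EVPI formula is applied to the fitted values, clipped at zero.  A nested
two-level Monte Carlo estimator serves as the cross-check at toy scale; the
regression estimator can exceed the sampled EVPI slightly (smoothing bias),
which the tests tolerate at 10%.

**One-way sensitivity analysis** re-runs the deterministic model with each
parameter at the ends of its interval, reusing the same simulation seed so
ICER differences reflect the parameter change only.

## Synthetic data

**Cohort generator.**  The 69-patient cohort emulates the UK placebo-arm
participants: age ~ Normal(61, 9) truncated at 30; 80% male; baseline EQ-5D
~ Normal(0.82, 0.15) truncated to the index range; 25% ectopic-disease
prevalence; baseline FD ~ Uniform(0, 20)° (the inclusion criterion caps it
at 30°).  The real trial's baseline covariate distributions are unpublished,
so these defaults are documented assumptions, editable via `CohortSpec`;
none of the package's outputs should be read as estimates of that trial's
actual baseline structure.

**Within-trial generator.**  Participant-level mean utilities and visit
utilities are drawn from Beta distributions rescaled to [−0.594, 1], so
expectations are exact without clipping bias; the configured arm QALY effect
is injected through a per-visit shift sized by the trapezoid weights.
Defaults reproduce the headline 12-month marginals (QALYs ≈ 0.875 vs 0.855,
adalimumab injection costs ≈ £2,030 vs 0, other NHS use negligible).  The
synthetic data are complete; the missing-data imputation used on the real
trial is out of scope here.  Near the EQ-5D ceiling an injected effect is
necessarily attenuated (utilities cannot exceed 1); parameter-recovery
checks therefore inject effects away from the ceiling.

What passing tests show — and do not show.  The generators reproduce
published *marginals* under the model's own assumptions; they do not carry
the real trial's correlation structure, missingness, site effects or
protocol deviations.  Tests demonstrate the estimators and the simulation
machinery are correct and calibrated to the published summaries, not that
the synthetic cohort is exchangeable with the real one.

## Placeholder inputs and their one-off calibration

The late-stage pathway probabilities, procedure costs, utility decrements,
and the mortality specification are not published in the source material
available to this package.  They ship in `late_stage_defaults.yaml` with
`provenance: placeholder_literature`, and were calibrated **once** against
the published base case — standard-care lifetime operations (1.36), model-
period cost (£1,416), and life expectancy (22.6 y) — then frozen.  After
calibration the deterministic base case gives: standard-care operations
1.36, model cost ≈ £1,385, repeated-courses ICER ≈ £12.9k/QALY, mean courses
3.43.  These placeholders are ordinary configuration inputs; every analysis
accepts a user file overriding them.

## Numerical choices

* FD floored at 0°; no hyperextension modelled.
* Late-stage entry FD is set to threshold + 10° (bookkeeping only — late
  utilities are state-based).
* Quiescence reactivation triggers at the first cycle start at or beyond
  `trial_end + k × quiescence_duration` (tolerance 1e−9).
* Degenerate inputs: empty cohorts, zero-length subsets, fewer than two
  strategies/draws and negative times raise explicit errors; a probability
  of 1 or 0 is honoured exactly.
* Bootstrap: resampling within arm, 5,000 replicates by default; replicates
  with an exactly zero QALY difference stay in the net-benefit CEAC and are
  excluded from ratio summaries.

## Known limitations

* Single-nodule disease only; no bilateral or multi-nodule modelling, no
  referral-volume effects, no societal costs.
* The late-stage pathway parameters are assumptions; absolute cost and QALY
  levels (as opposed to incremental comparisons under common random numbers)
  inherit that uncertainty directly.
* Comparators other than standard care (radiotherapy, steroid injections)
  are not implemented — their parameters are not published in usable form.
* EVPPI is a smoothed estimator; for small draw counts its bias can be of
  the same order as the quantity itself.
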