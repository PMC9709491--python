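# dupsim

Patient-level cost-effectiveness modelling of **intranodular adalimumab for
progressive early-stage Dupuytren's disease (DD)**, from a UK NHS
perspective.  The package is aimed at health economists and methodologists
who want a fully reproducible, synthetic-data implementation of an early
(pre-licensing) economic evaluation: a within-trial cost-utility analysis, a
lifetime individual-patient simulation, probabilistic sensitivity analysis
(PSA), cost-effectiveness acceptability curves (CEAC) and value-of-
information analysis.

## The model in brief

Disease history is simulated in 6-month cycles from randomization to a
55-year horizon.  At 18 months each patient is progressive, quiescent or
late-stage with arm-specific probabilities.  Progressive patients' flexion
deformity follows a Gaussian random walk (18-month drift 0.8631°, +8.5189°
with ectopic disease, RMSE 12.6079°, scaled per cycle as mean/3, SD/√3);
crossing 30° is permanent late-stage disease, which opens a surgical pathway
(≤3 needle fasciotomies, ≤1 limited fasciectomy, ≤1 dermofasciectomy).
Quiescent patients are stable for 3 years; under the retreatment strategy a
new course of four £475 injections maintains quiescence indefinitely.
Costs and QALYs beyond the 18-month trial window are discounted at 3.5%/yr;
utilities come from a published regression (constant 0.3847, baseline-utility
coefficient 0.5410, quiescence gain 0.0395).  Decision quantities use net
monetary benefit NB = λ·QALYs − cost:

* **ICER** between strategies, with strict and extended dominance on the
  cost-sorted frontier;
* **CEAC**: P(strategy maximizes NB) across PSA draws, per λ;
* **EVPI** = E[max NB] − max E[NB] per patient, scaled to the 2,584,411 UK
  prevalent cases; **EVPPI** for parameter subsets by single-loop spline
  regression.

See `docs/methods.md` for the full model description, distributional
choices and limitations.  All individual-level data are synthetic — the
generators are first-class, tested package code.

## Worked example

```python
import dupsim
from dupsim.psa import evaluate_strategies, mean_outcomes, pairwise_icer

params = dupsim.load_parameters()          # packaged defaults, all provenance-tagged
cohort = dupsim.generate_cohort(seed=1)    # 69 synthetic placebo-arm patients
means = mean_outcomes(evaluate_strategies(cohort, params, n_reps=200, seed=7))
print(means[["cost_lifetime", "qalys_lifetime", "courses", "operations"]].round(3))
print(round(pairwise_icer(means, "adalimumab_repeat", "standard_care")))
```

prints

```
                   cost_lifetime  qalys_lifetime  courses  operations
strategy
standard_care           1675.489          12.289    0.000       1.359
adalimumab_once         3503.119          12.339    1.000       1.312
adalimumab_repeat       6100.307          12.632    3.451       0.901
12895
```

Read: repeated courses cost £6,100 and yield 12.63 discounted lifetime QALYs
per patient versus £1,675 and 12.29 under standard care — an ICER of
£12,895 per QALY gained, below the £20,000/QALY threshold the NHS
conventionally applies, with 0.46 operations for late-stage disease averted.
A probabilistic run (`dupsim.run_base_case(scale="desk", seed=1)`) puts the
probability that repeated adalimumab is best value for money at ~0.79 at
£20,000/QALY, and the per-patient EVPI at ~£217.

The `examples/` directory has one short script per capability: a single
patient's trajectory, the deterministic base case, PSA + CEAC + EVPI/EVPPI,
the one-way sensitivity tornado, and the within-trial bootstrap analysis.
A thin CLI mirrors them: `dupsim psa --scale desk --seed 1`,
`dupsim within-trial`, `dupsim tornado`, `dupsim make-cohort`.

## Configuration

Every model input lives in YAML with a point estimate, an optional 95%
interval driving the PSA, and a provenance tag.  User files merge over the
packaged defaults, so a one-line file overrides a single input.  Late-stage
pathway and mortality inputs are clearly-labelled placeholders
(`late_stage_defaults.yaml`) — documented assumptions, calibrated once to
the published base case and editable like any other input.
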