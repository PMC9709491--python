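"""Probabilistic sensitivity analysis, acceptability curves and EVPI.

A reduced-size PSA (100 parameter draws x 10 repetitions per patient) is run
end-to-end; at each willingness-to-pay the CEAC gives the probability that
each strategy is best value for money, and the per-patient EVPI is the most
the NHS should pay, per prevalent case, for research removing all parameter
uncertainty.
"""

import dupsim
from dupsim.psa import ceac, evpi_per_patient, evppi, population_value, run_psa

params = dupsim.load_parameters()
cohort = dupsim.generate_cohort(seed=1)
draws = dupsim.sample_psa(params, n_draws=100, seed=2)
samples = run_psa(cohort, draws, n_reps=10, seed=3)

curves = ceac(samples, [0, 10000, 20000, 30000, 50000])
print(curves.pivot(index="wtp", columns="strategy", values="probability").round(2).to_string())

for wtp in (20000.0, 30000.0):
    evpi = evpi_per_patient(samples, wtp)
    pop = population_value(evpi, params.uk_prevalent_cases)
    print(f"\nEVPI at GBP {wtp:,.0f}/QALY: GBP {evpi:,.0f} per patient "
          f"(GBP {pop/1e6:,.0f} million over all UK prevalent cases)")

partial = evppi(samples, list(dupsim.RIDD_PARAMETERS), 20000.0)
print(f"EVPPI of the trial-estimated parameters + quiescence duration: GBP {partial:,.0f} per patient")
print("(the most a confirmatory trial resolving those parameters could be worth)")
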