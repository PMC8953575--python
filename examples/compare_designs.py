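"""Operating characteristics of five designs on one alternative scenario.

Replicates trials under scenario 10 (overall event rate 0.31 on the
experimental arm vs 0.50 on control) for each design and tabulates
rejection probability (power), allocation imbalance, and expected
failures.  A small replicate count keeps this demo quick; the published
study uses 1000 replicates.
"""

import pandas as pd

from caratrial import Design, get_scenario, operating_characteristics

scenario = get_scenario(10)
rows = []
for design in Design:
    oc = operating_characteristics(
        scenario,
        design,
        n_reps=100,
        master_seed=7,
        mcmc_iterations=2_000,
        mcmc_burn_in=1_000,
    )
    rows.append(
        {
            "design": design.value,
            "power": oc.rejection_prob,
            "mean nA-nB": round(oc.mean_alloc_diff, 1),
            "mean failures": round(oc.mean_failures, 1),
            "mean enrolled": round(oc.mean_n_enrolled, 1),
        }
    )
print(pd.DataFrame(rows).to_string(index=False))

print(
    "\nAdaptive designs shift patients toward the better arm (positive"
    "\nnA-nB) and the Bayesian-monitored design (bacara) combines that"
    "\nskew with early stopping, giving the lowest expected failures at"
    "\ncomparable power."
)
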