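"""Why personalized allocation breaks the conventional sequential test.

Scenario 5 is a null scenario — the arms are identical — but covariate
x2 strongly drives the outcome (beta = (-1, 0, 2)).  Personalized
randomization reacts to that prognostic signal, unbalancing the
subgroup mix across arms, and the conventional chi-square sequential
test then rejects far too often.  The subgroup-averaged Bayesian test
repairs this.
"""

from caratrial import Design, get_scenario, operating_characteristics

scenario = get_scenario(5)
for design in (Design.TRAD, Design.CARA1, Design.BACARA):
    oc = operating_characteristics(
        scenario,
        design,
        n_reps=200,
        master_seed=11,
        mcmc_iterations=2_000,
        mcmc_burn_in=1_000,
    )
    print(f"{design.value:>7}: null rejection rate = {oc.rejection_prob:.3f}")

print(
    "\nNominal level is 0.05.  Fixed randomization (trad) holds it;"
    "\npersonalized allocation with the conventional test (cara1)"
    "\ninflates it several-fold; the same allocation monitored with the"
    "\nsubgroup-averaged posterior statistic (bacara) restores control."
)
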