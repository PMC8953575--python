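"""Analytic event rates for the built-in scenarios.

Every scenario is a set of probit coefficients (beta for prognostic
main effects, gamma for the treatment effect and its interactions).
This prints the exact per-subgroup and overall event probabilities
(pA, pB) they imply — the quantities the simulator's Monte Carlo
estimates converge to.
"""

from caratrial import get_scenario, true_effect_table

for sc_id in (1, 5, 10, 20):
    sc = get_scenario(sc_id)
    print(f"\nscenario {sc.id}: beta={sc.params.beta}, gamma={sc.params.gamma}")
    print(true_effect_table(sc).round(3))

print(
    "\npA/pB are event (failure) rates on the experimental/control arm;"
    "\nrows show the four covariate subgroups and their prevalence-weighted"
    "\noverall average. gamma = 0 (scenario 1, 5) forces pA = pB: no"
    "\ntreatment effect; scenario 20 mixes subgroups that benefit from A"
    "\nwith one that benefits from B."
)
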