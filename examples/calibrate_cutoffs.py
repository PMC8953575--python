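"""Calibrating the posterior probability cutoffs by simulation.

The Bayesian stopping rule depends on three cutoffs: eps1 (interim
superiority), eps2 (interim futility) and eps3 (final superiority).
They are tuned by simulation so the design holds frequentist error
rates: type I error on null scenarios, power on a reference
alternative.  This demo runs a deliberately tiny calibration (few
replicates, short chains) to show the mechanics and the iteration
trace; a real calibration uses hundreds of replicates per iteration.
"""

from caratrial import calibrate_cutoffs, get_scenario

result = calibrate_cutoffs(
    null_scenarios=[get_scenario(1), get_scenario(5)],
    reference_alternative=get_scenario(10),
    alpha=0.05,
    beta=0.2,
    n_reps=40,
    master_seed=3,
    max_iterations=4,
    mcmc_iterations=1_000,
    mcmc_burn_in=500,
)

print(f"cutoffs: eps1={result.eps1:.3f} eps2={result.eps2:.3f} eps3={result.eps3:.3f}")
print(f"worst null rejection: {max(result.type1_by_scenario.values()):.3f}")
print(f"power on reference alternative: {result.power:.3f}")
print(f"converged: {result.converged}")
for step in result.trace:
    print(
        "  iter {iteration}: eps=({eps1:.3f}, {eps2:.3f}, {eps3:.3f}) "
        "type1={worst_type1:.3f} power={power:.3f}".format(**step)
    )

print(
    "\nEach iteration simulates the design at the current cutoffs with"
    "\ncommon random numbers; cutoffs move up when error rates overshoot"
    "\ntheir targets and down when they undershoot, with halving steps."
)
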