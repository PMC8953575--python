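"""Operating characteristics over replicated trials, and cutoff calibration.

Replicates are independent given the master seed: replicate ``i`` derives
its own random streams from ``(master_seed, i)``, so results do not
depend on execution order and different designs can be compared on
common patient streams by sharing the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allocation import Design
from .engine import TrialConfig, TrialResult, run_trial
from .monitoring import MonitoringConfig
from .scenarios import Scenario, subgroup_profiles

__all__ = [
    "OCSummary",
    "CalibrationResult",
    "operating_characteristics",
    "calibrate_cutoffs",
    "summarize_to_tables",
]


@dataclass
class OCSummary:
    """Aggregated frequency properties of one (scenario, design) cell."""

    scenario_id: int
    design: Design
    n_reps: int
    rejection_prob: float
    mean_alloc_diff: float
    mean_failures: float
    #: per (profile, arm): mean and SD across trials of the fraction of
    #: enrolled patients landing in that subgroup-arm cell
    subgroup_alloc_mean: dict[tuple[tuple[int, ...], int], float]
    subgroup_alloc_sd: dict[tuple[tuple[int, ...], int], float]
    early_stop_fractions: dict[int, float]
    mean_n_enrolled: float
    degenerate_fit_rate: float


def operating_characteristics(
    scenario: Scenario,
    design: Design,
    n_reps: int,
    master_seed: int,
    cohort_sizes: tuple[int, ...] = (70, 70, 70),
    monitoring: MonitoringConfig | None = None,
    mcmc_iterations: int = 10_000,
    mcmc_burn_in: int = 5_000,
) -> OCSummary:
    """Estimate operating characteristics from ``n_reps`` simulated trials."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    config = TrialConfig(
        scenario=scenario,
        design=Design(design),
        cohort_sizes=tuple(cohort_sizes),
        monitoring=monitoring or MonitoringConfig(),
        mcmc_iterations=mcmc_iterations,
        mcmc_burn_in=mcmc_burn_in,
        seed=master_seed,
    )
    results = [run_trial(config, replicate=i) for i in range(n_reps)]
    return summarize_results(results)


def summarize_results(results: list[TrialResult]) -> OCSummary:
    """Aggregate a list of per-trial results into an OCSummary."""
    if not results:
        raise ValueError("no trial results to summarize")
    config = results[0].config
    d = config.scenario.params.d
    keys = [(p, g) for p in subgroup_profiles(d) for g in (1, 0)]
    fractions = {
        key: np.array([r.subgroup_alloc[key] / r.n_enrolled for r in results])
        for key in keys
    }
    n_stages = config.n_stages
    stops = {
        k: float(np.mean([r.stop_stage == k and r.decision.verdict.is_stop for r in results]))
        for k in range(1, n_stages)
    }
    return OCSummary(
        scenario_id=config.scenario.id,
        design=config.design,
        n_reps=len(results),
        rejection_prob=float(np.mean([r.rejected for r in results])),
        mean_alloc_diff=float(np.mean([r.alloc_diff for r in results])),
        mean_failures=float(np.mean([r.failures for r in results])),
        subgroup_alloc_mean={k: float(v.mean()) for k, v in fractions.items()},
        subgroup_alloc_sd={k: float(v.std(ddof=1)) if len(results) > 1 else 0.0 for k, v in fractions.items()},
        early_stop_fractions=stops,
        mean_n_enrolled=float(np.mean([r.n_enrolled for r in results])),
        degenerate_fit_rate=float(np.mean([r.degenerate_fits > 0 for r in results])),
    )


@dataclass
class CalibrationResult:
    eps1: float
    eps2: float
    eps3: float
    type1_by_scenario: dict[int, float]
    power: float
    converged: bool
    trace: list[dict] = field(default_factory=list)


def calibrate_cutoffs(
    null_scenarios: list[Scenario],
    reference_alternative: Scenario,
    alpha: float = 0.05,
    beta: float = 0.2,
    n_reps: int = 500,
    master_seed: int = 0,
    initial_step: float = 0.01,
    max_iterations: int = 20,
    type1_tol: float = 0.01,
    power_tol: float = 0.02,
    **oc_kwargs,
) -> CalibrationResult:
    """Iteratively calibrate the posterior cutoffs (eps1, eps2, eps3).

    Starting from eps1 = eps3 = 1 - alpha and eps2 = 1 - beta, each
    round estimates the worst type I error across the null scenarios and
    the power on the reference alternative by simulation with common
    random numbers, then nudges the cutoffs: type I error above target
    raises eps1/eps3 (harder to claim superiority), below target lowers
    them; power below target raises eps2 (harder to stop for futility).
    The step halves whenever an adjustment reverses direction, and the
    search stops once both error rates sit inside their tolerance bands
    or the iteration cap is hit (returned flagged as non-converged).
    """
    eps1 = eps3 = 1.0 - alpha
    eps2 = 1.0 - beta
    step1 = step2 = initial_step
    last_dir1 = last_dir2 = 0
    trace: list[dict] = []
    best = None

    def evaluate(e1: float, e2: float, e3: float):
        cfg = MonitoringConfig(eps1=e1, eps2=e2, eps3=e3, alpha=alpha)
        t1 = {
            sc.id: operating_characteristics(
                sc, Design.BACARA, n_reps, master_seed, monitoring=cfg, **oc_kwargs
            ).rejection_prob
            for sc in null_scenarios
        }
        pw = operating_characteristics(
            reference_alternative, Design.BACARA, n_reps, master_seed, monitoring=cfg, **oc_kwargs
        ).rejection_prob
        return t1, pw

    converged = False
    for it in range(max_iterations):
        t1, power = evaluate(eps1, eps2, eps3)
        worst_t1 = max(t1.values())
        trace.append(
            {"iteration": it, "eps1": eps1, "eps2": eps2, "eps3": eps3,
             "worst_type1": worst_t1, "power": power}
        )
        t1_ok = worst_t1 <= alpha + type1_tol
        power_ok = power >= 1.0 - beta - power_tol
        score = max(0.0, worst_t1 - alpha - type1_tol) + max(0.0, (1 - beta - power_tol) - power)
        if best is None or score < best[0]:
            best = (score, eps1, eps2, eps3, t1, power)
        if t1_ok and power_ok:
            converged = True
            break
        # direction: +1 means raise the cutoff
        dir1 = 1 if worst_t1 > alpha + type1_tol else (-1 if worst_t1 < alpha - type1_tol else 0)
        dir2 = 1 if not power_ok else 0
        if dir1 and last_dir1 and dir1 != last_dir1:
            step1 /= 2.0
        if dir2 and last_dir2 and dir2 != last_dir2:
            step2 /= 2.0
        if dir1:
            eps1 = float(np.clip(eps1 + dir1 * step1, 0.5, 1 - 1e-4))
            eps3 = float(np.clip(eps3 + dir1 * step1, 0.5, 1 - 1e-4))
            last_dir1 = dir1
        if dir2:
            eps2 = float(np.clip(eps2 + dir2 * step2, 0.5, 1 - 1e-4))
            last_dir2 = dir2
        if not dir1 and not dir2 and not (t1_ok and power_ok):
            break  # inside dead band yet targets unmet: cannot improve

    _, e1, e2, e3, t1, power = best
    return CalibrationResult(
        eps1=e1, eps2=e2, eps3=e3, type1_by_scenario=t1, power=power,
        converged=converged, trace=trace,
    )


def summarize_to_tables(summaries: list[OCSummary]) -> dict[str, pd.DataFrame]:
    """Arrange OC summaries into the three standard report tables.

    ``rejection``: scenario x design rejection probabilities.
    ``allocation``: per (scenario, design, arm) subgroup allocation
    fractions, mean (SD) across trials.
    ``operating``: scenario x design mean nA - nB and mean failures.
    """
    designs = [d.value for d in Design]
    present = sorted({s.design.value for s in summaries}, key=designs.index)
    scenarios = sorted({s.scenario_id for s in summaries})
    by_cell = {(s.scenario_id, s.design.value): s for s in summaries}

    rej = pd.DataFrame(index=pd.Index(scenarios, name="sc"), columns=present, dtype=float)
    diff = pd.DataFrame(index=pd.Index(scenarios, name="sc"), columns=present, dtype=float)
    fail = pd.DataFrame(index=pd.Index(scenarios, name="sc"), columns=present, dtype=float)
    alloc_rows = []
    for (sc, dg), s in by_cell.items():
        rej.loc[sc, dg] = s.rejection_prob
        diff.loc[sc, dg] = s.mean_alloc_diff
        fail.loc[sc, dg] = s.mean_failures
        profiles = sorted({p for (p, _) in s.subgroup_alloc_mean}, reverse=True)
        for arm in (1, 0):
            row = {"sc": sc, "design": dg, "arm": "A" if arm else "B"}
            for p in profiles:
                mean = s.subgroup_alloc_mean[(p, arm)]
                sd = s.subgroup_alloc_sd[(p, arm)]
                row[str(p)] = f"{mean:.3f} ({sd:.3f})"
            alloc_rows.append(row)
    allocation = pd.DataFrame(alloc_rows)
    operating = pd.concat({"alloc_diff": diff, "failures": fail}, axis=1)
    return {"rejection": rej, "allocation": allocation, "operating": operating}
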