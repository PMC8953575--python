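"""Single-trial simulation engine.

One call to :func:`run_trial` plays out a complete group sequential
trial: the first cohort is randomized 1:1 (the burn-in stage), outcomes
are observed, and the stage-1 analysis runs.  On a continue decision the
design's allocation rule is refreshed from all accumulated data and the
next cohort is enrolled with the frozen rule; the cycle repeats until an
early stop or the final analysis at the last cohort.

Designs differ along two axes:

========  =========================  =================================
design    allocation after burn-in   monitoring
========  =========================  =================================
trad      fixed 1:1                  OBF chi-square sequential test
rar       sqrt-rule on success rates OBF chi-square sequential test
cara1     posterior Pr(pA < pB | x)  OBF chi-square sequential test
cara2     1 - posterior mean rates   OBF chi-square sequential test
bacara    same as cara1              Bayesian subgroup-averaged T_k
========  =========================  =================================

Comparator designs stop early only on a significant chi-square
difference; the Bayesian rule stops for superiority or futility.  Outcomes are assumed fully observed before the
next cohort enrolls.

Randomness is split into named per-trial streams (covariates, outcomes,
assignments, MCMC) derived from ``(seed, replicate, stream)``, so
different designs run on a common patient stream: the same replicate
sees the same covariates, the same assignment uniforms, and the same
outcome uniforms under either arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import allocation as alloc
from .allocation import Design
from .inference import (
    PatientData,
    PosteriorDraws,
    default_prior,
    fit_mle,
    posterior_mean_rates,
    posterior_prob_benefit,
    sample_posterior,
)
from .monitoring import (
    Decision,
    MonitoringConfig,
    Verdict,
    bayes_decision,
    comparator_boundaries,
    comparator_test,
    empirical_weights,
    test_statistic_draws,
)
from .scenarios import Scenario, response_probability, subgroup_profiles

__all__ = ["TrialConfig", "TrialResult", "AllocationRule", "run_trial", "randomize_cohort"]

logger = logging.getLogger(__name__)

_STREAMS = {"covariates": 0, "outcomes": 1, "assignments": 2, "mcmc": 3}


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to reproduce one trial."""

    scenario: Scenario
    design: Design
    cohort_sizes: tuple[int, ...] = (70, 70, 70)
    monitoring: MonitoringConfig = field(default_factory=MonitoringConfig)
    mcmc_iterations: int = 10_000
    mcmc_burn_in: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.cohort_sizes)
        object.__setattr__(self, "cohort_sizes", sizes)
        object.__setattr__(self, "design", Design(self.design))
        if len(sizes) < 2 or any(n <= 0 for n in sizes):
            raise ValueError("need at least two cohorts of positive size")

    @property
    def n_stages(self) -> int:
        return len(self.cohort_sizes)

    @property
    def max_n(self) -> int:
        return sum(self.cohort_sizes)

    @property
    def info_fractions(self) -> tuple[float, ...]:
        cum = np.cumsum(self.cohort_sizes)
        return tuple(float(c) / self.max_n for c in cum)


@dataclass(frozen=True)
class AllocationRule:
    """The allocation rule frozen at an interim, applied to the next cohort."""

    kind: Design
    probs_by_profile: dict[tuple[int, ...], float] | None = None
    prob_a: float = 0.5

    def prob(self, profile) -> float:
        if self.probs_by_profile is None:
            return self.prob_a
        return self.probs_by_profile[tuple(int(v) for v in np.ravel(profile))]


@dataclass
class TrialResult:
    """Outcome and bookkeeping of one simulated trial."""

    config: TrialConfig
    decision: Decision
    stop_stage: int
    n_enrolled: int
    n_a: int
    n_b: int
    failures: int
    subgroup_alloc: dict[tuple[tuple[int, ...], int], int]
    alloc_prob_trace: list[dict[tuple[int, ...], float]]
    interim_decisions: list[Decision]
    degenerate_fits: int = 0

    @property
    def rejected(self) -> bool:
        return self.decision.verdict.is_rejection

    @property
    def alloc_diff(self) -> int:
        """nA - nB at trial end."""
        return self.n_a - self.n_b


def _stream_rng(seed: int, replicate: int, stream: str, stage: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(replicate), _STREAMS[stream], int(stage)))
    )


def randomize_cohort(rule: AllocationRule, profiles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign each patient to arm A by an independent Bernoulli draw
    with the rule's probability at that patient's covariate profile."""
    profiles = np.atleast_2d(np.asarray(profiles))
    probs = np.array([rule.prob(row) for row in profiles])
    return (rng.random(profiles.shape[0]) < probs).astype(np.int64)


def _fit_posterior(data: PatientData, config: TrialConfig, rng: np.random.Generator):
    """One regression fit per interim: MLE-centred prior, then Gibbs."""
    mle = fit_mle(data)
    prior = default_prior(mle.params)
    seed = int(rng.integers(2**31))
    post = sample_posterior(
        data,
        prior,
        iterations=config.mcmc_iterations,
        burn_in=config.mcmc_burn_in,
        seed=seed,
    )
    return post, mle.degenerate


def _cara_rule(design: Design, posterior: PosteriorDraws, d: int) -> AllocationRule:
    probs: dict[tuple[int, ...], float] = {}
    for profile in subgroup_profiles(d):
        if design in (Design.CARA1, Design.BACARA):
            probs[profile] = alloc.prob_cara1(posterior_prob_benefit(posterior, profile))
        else:
            pa, pb = posterior_mean_rates(posterior, profile)
            probs[profile] = alloc.prob_cara2(pa, pb)
    return AllocationRule(kind=design, probs_by_profile=probs)


def run_trial(config: TrialConfig, replicate: int = 0) -> TrialResult:
    """Simulate one complete trial under the configured design."""
    scenario = config.scenario
    design = config.design
    d = scenario.params.d
    boundaries = comparator_boundaries(config.monitoring.alpha, config.info_fractions)

    cov_rng = _stream_rng(config.seed, replicate, "covariates")
    out_rng = _stream_rng(config.seed, replicate, "outcomes")
    asn_rng = _stream_rng(config.seed, replicate, "assignments")
    mcmc_rng = _stream_rng(config.seed, replicate, "mcmc")

    x_all: list[np.ndarray] = []
    arm_all: list[np.ndarray] = []
    y_all: list[np.ndarray] = []
    cohort_all: list[np.ndarray] = []
    cohort_weights: list[dict[tuple[int, ...], float]] = []
    cohort_sizes_seen: list[int] = []
    alloc_trace: list[dict[tuple[int, ...], float]] = []
    interim_decisions: list[Decision] = []
    degenerate_fits = 0

    rule = AllocationRule(kind=design)  # burn-in cohort: 1:1 for every design
    decision: Decision | None = None

    for k, n_k in enumerate(config.cohort_sizes, start=1):
        profiles = (cov_rng.random((n_k, d)) < scenario.covariate_dist).astype(np.int64)
        arms = randomize_cohort(rule, profiles, asn_rng)
        probs_event = response_probability(scenario.params, arms, profiles)
        outcomes = (out_rng.random(n_k) < probs_event).astype(np.int64)

        alloc_trace.append(
            {p: rule.prob(p) for p in subgroup_profiles(d)}
        )
        x_all.append(profiles)
        arm_all.append(arms)
        y_all.append(outcomes)
        cohort_all.append(np.full(n_k, k))
        cohort_weights.append(empirical_weights(profiles))
        cohort_sizes_seen.append(n_k)

        data = PatientData(
            x=np.vstack(x_all),
            arm=np.concatenate(arm_all),
            y=np.concatenate(y_all),
            cohort=np.concatenate(cohort_all),
        )

        posterior: PosteriorDraws | None = None
        if design is Design.BACARA:
            posterior, flagged = _fit_posterior(data, config, mcmc_rng)
            degenerate_fits += int(flagged)
            tk = test_statistic_draws(posterior, cohort_sizes_seen, cohort_weights)
            decision = bayes_decision(tk, config.monitoring, k, config.n_stages)
        else:
            on_a = data.arm == 1
            decision = comparator_test(
                events_a=int(data.y[on_a].sum()),
                n_a=int(on_a.sum()),
                events_b=int(data.y[~on_a].sum()),
                n_b=int((~on_a).sum()),
                boundary=boundaries[k - 1],
                stage=k,
                n_stages=config.n_stages,
            )
        interim_decisions.append(decision)
        if decision.verdict.is_stop:
            break

        # continue: refresh the allocation rule for the next cohort
        if design is Design.TRAD:
            rule = AllocationRule(kind=design)
        elif design is Design.RAR:
            on_a = data.arm == 1
            q_a = 1.0 - data.y[on_a].mean() if on_a.any() else 0.5
            q_b = 1.0 - data.y[~on_a].mean() if (~on_a).any() else 0.5
            rule = AllocationRule(kind=design, prob_a=alloc.prob_rar(q_a, q_b))
        else:  # CARA1 / CARA2 / BACARA
            if posterior is None:
                posterior, flagged = _fit_posterior(data, config, mcmc_rng)
                degenerate_fits += int(flagged)
            rule = _cara_rule(design, posterior, d)

    assert decision is not None
    x = np.vstack(x_all)
    arm = np.concatenate(arm_all)
    y = np.concatenate(y_all)
    subgroup_alloc: dict[tuple[tuple[int, ...], int], int] = {}
    for profile in subgroup_profiles(d):
        mask = np.all(x == np.asarray(profile), axis=1)
        for g in (1, 0):
            subgroup_alloc[(profile, g)] = int(np.sum(mask & (arm == g)))

    logger.debug(
        "trial sc=%s design=%s rep=%d: %s at stage %d, n=%d, failures=%d",
        scenario.id, design.value, replicate, decision.verdict.value,
        decision.stage, y.size, int(y.sum()),
    )
    return TrialResult(
        config=config,
        decision=decision,
        stop_stage=decision.stage,
        n_enrolled=int(y.size),
        n_a=int((arm == 1).sum()),
        n_b=int((arm == 0).sum()),
        failures=int(y.sum()),
        subgroup_alloc=subgroup_alloc,
        alloc_prob_trace=alloc_trace,
        interim_decisions=interim_decisions,
        degenerate_fits=degenerate_fits,
    )
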