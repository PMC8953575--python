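"""Sequential monitoring: the Bayesian subgroup-averaged test and the
conventional group sequential comparator.

Two testing machineries live here.

**Subgroup-averaged Bayesian test.**  For cohort k with observed
subgroup prevalences w_i, the cohort-level contrast is

    Delta_k(theta) = sum_i [Phi(x_i~' beta + x_i~' gamma) - Phi(x_i~' beta)] w_i,

the prevalence-weighted difference in event rates between arms, and the
sequential statistic is the cohort-size-weighted running average

    T_k = sum_{j<=k} n_j Delta_j / sum_{j<=k} n_j.

Both are functions of theta, so their posterior distribution is obtained
by evaluating them over posterior draws.  The trial stops early for
superiority when Pr(T_k < delta1 | data) > eps1, for futility when
Pr(T_k > delta2 | data) > eps2, and claims superiority at the final look
when Pr(T_K < delta1 | data) > eps3.  Negative T_k favours arm A
(fewer events).

**Comparator group sequential test.**  The conventional designs monitor
the two-proportion chi-square statistic — equivalently the absolute
signed z statistic — against symmetric O'Brien-Fleming boundaries from
the Lan-DeMets spending function at overall level alpha (alpha/2 spent
per side), stopping early only when the difference is significant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .inference import PosteriorDraws
from .scenarios import RegressionParams

__all__ = [
    "Verdict",
    "Decision",
    "MonitoringConfig",
    "SubgroupWeights",
    "empirical_weights",
    "delta_k",
    "delta_draws",
    "test_statistic_draws",
    "bayes_decision",
    "obf_spending",
    "obf_boundaries",
    "comparator_test",
]

#: Mapping from covariate profile (tuple of 0/1) to its prevalence weight.
SubgroupWeights = Mapping[tuple[int, ...], float]


class Verdict(str, enum.Enum):
    CONTINUE = "continue"
    STOP_SUPERIOR = "stop_superior"
    STOP_FUTILE = "stop_futile"
    FINAL_SUPERIOR = "final_superior"
    FINAL_NOT_SUPERIOR = "final_not_superior"

    @property
    def is_stop(self) -> bool:
        return self is not Verdict.CONTINUE

    @property
    def is_rejection(self) -> bool:
        """Did the trial declare A superior (early or at the final look)?"""
        return self in (Verdict.STOP_SUPERIOR, Verdict.FINAL_SUPERIOR)


@dataclass(frozen=True)
class Decision:
    verdict: Verdict
    stage: int
    prob_superior: float | None = None
    prob_futile: float | None = None
    statistic: float | None = None
    boundary: float | None = None
    flag: str | None = None


@dataclass(frozen=True)
class MonitoringConfig:
    """Stopping-rule parameters for both testing machineries.

    delta1/delta2 are the superiority and futility margins on the event
    rate difference T_k (0 by default: any improvement counts).
    eps1/eps2/eps3 are the calibrated posterior-probability cutoffs; the
    shipped defaults (0.995, 0.75, 0.98) hold one-sided type I error at
    0.05 for the built-in null scenarios.  ``alpha`` is the one-sided
    level of the comparator group sequential test.
    """

    delta1: float = 0.0
    delta2: float = 0.0
    eps1: float = 0.995
    eps2: float = 0.75
    eps3: float = 0.98
    alpha: float = 0.05
    info_fractions: tuple[float, ...] = (1 / 3, 2 / 3, 1.0)

    def __post_init__(self) -> None:
        for name in ("eps1", "eps2", "eps3"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        fr = tuple(float(t) for t in self.info_fractions)
        object.__setattr__(self, "info_fractions", fr)
        if abs(fr[-1] - 1.0) > 1e-12:
            raise ValueError("info_fractions must end at 1")


def empirical_weights(profiles: np.ndarray) -> dict[tuple[int, ...], float]:
    """Observed subgroup prevalences within one cohort of profiles."""
    profiles = np.atleast_2d(np.asarray(profiles))
    n = profiles.shape[0]
    weights: dict[tuple[int, ...], float] = {}
    for row in profiles:
        key = tuple(int(v) for v in row)
        weights[key] = weights.get(key, 0.0) + 1.0 / n
    return weights


def _weights_arrays(weights: SubgroupWeights) -> tuple[np.ndarray, np.ndarray]:
    keys = list(weights.keys())
    xt = np.hstack([np.ones((len(keys), 1)), np.asarray(keys, dtype=float)])
    w = np.asarray([weights[k] for k in keys], dtype=float)
    return xt, w


def delta_k(theta: RegressionParams, weights: SubgroupWeights) -> float:
    """Subgroup-averaged treatment contrast Delta_k at one parameter value."""
    xt, w = _weights_arrays(weights)
    diff = ndtr(xt @ theta.beta + xt @ theta.gamma) - ndtr(xt @ theta.beta)
    return float(w @ diff)


def delta_draws(posterior: PosteriorDraws, weights: SubgroupWeights) -> np.ndarray:
    """Delta_k evaluated at every posterior draw (vectorised)."""
    xt, w = _weights_arrays(weights)
    eta_b = posterior.beta_draws @ xt.T  # (M, s)
    eta_g = posterior.gamma_draws @ xt.T
    return (ndtr(eta_b + eta_g) - ndtr(eta_b)) @ w


def test_statistic_draws(
    posterior: PosteriorDraws,
    cohort_sizes: Sequence[int],
    cohort_weights: Sequence[SubgroupWeights],
) -> np.ndarray:
    """Posterior draws of T_k = sum_j n_j Delta_j / sum_j n_j.

    Each cohort's Delta_j uses that cohort's own subgroup prevalences,
    evaluated under the current posterior.  Because Delta_j is linear in
    the weights, T_k equals Delta evaluated at the size-weighted average
    of the cohort weight vectors; that identity is used here.
    """
    sizes = np.asarray(cohort_sizes, dtype=float)
    if len(cohort_weights) != sizes.size:
        raise ValueError("cohort_sizes and cohort_weights lengths differ")
    if np.any(sizes <= 0):
        raise ValueError("cohort sizes must be positive")
    total = sizes.sum()
    merged: dict[tuple[int, ...], float] = {}
    for n_j, w_j in zip(sizes, cohort_weights):
        for key, w in w_j.items():
            merged[key] = merged.get(key, 0.0) + (n_j / total) * w
    return delta_draws(posterior, merged)


def bayes_decision(
    tk_draws: np.ndarray,
    config: MonitoringConfig,
    stage: int,
    n_stages: int,
) -> Decision:
    """Apply the Bayesian stopping rule to posterior draws of T_k.

    Superiority is checked before futility at interims; at the final
    stage only the superiority claim (cutoff eps3) is evaluated.
    """
    draws = np.asarray(tk_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("tk_draws must be non-empty")
    p_sup = float(np.mean(draws < config.delta1))
    p_fut = float(np.mean(draws > config.delta2))
    if stage < n_stages:
        if p_sup > config.eps1:
            verdict = Verdict.STOP_SUPERIOR
        elif p_fut > config.eps2:
            verdict = Verdict.STOP_FUTILE
        else:
            verdict = Verdict.CONTINUE
    else:
        verdict = Verdict.FINAL_SUPERIOR if p_sup > config.eps3 else Verdict.FINAL_NOT_SUPERIOR
    return Decision(verdict=verdict, stage=stage, prob_superior=p_sup, prob_futile=p_fut)


def obf_spending(alpha: float, t: float) -> float:
    """Lan-DeMets O'Brien-Fleming alpha spending function.

    f(t) = 2 (1 - Phi(Phi^{-1}(1 - alpha/2) / sqrt(t))), which spends
    almost nothing early and reaches exactly alpha at t = 1.
    """
    if t <= 0:
        return 0.0
    return float(2.0 * (1.0 - ndtr(ndtri(1.0 - alpha / 2.0) / np.sqrt(min(t, 1.0)))))


# Grid for the boundary recursion: range wide enough that the truncated
# mass beyond it is < 1e-12, spacing fine enough for ~1e-7 tail accuracy.
_GRID_LO, _GRID_HI, _GRID_N = -8.5, 8.5, 4251


@lru_cache(maxsize=None)
def obf_boundaries(alpha: float, info_fractions: tuple[float, ...]) -> tuple[float, ...]:
    """One-sided group sequential boundaries for OBF-spent alpha.

    Critical z-values c_1..c_K such that the standard Brownian-motion
    z-statistics (cov sqrt(t_i/t_j)) first cross c_k with cumulative
    probability equal to the spent alpha at each look.  Solved by the
    usual recursive numerical integration of the continuation density on
    a trapezoid grid.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    fr = np.asarray(info_fractions, dtype=float)
    if fr.ndim != 1 or fr.size == 0 or np.any(np.diff(fr) <= 0) or fr[0] <= 0:
        raise ValueError("info_fractions must be strictly increasing and positive")
    if abs(fr[-1] - 1.0) > 1e-12:
        raise ValueError("info_fractions must end at 1")

    spent = np.array([obf_spending(alpha, t) for t in fr])
    increments = np.diff(np.concatenate([[0.0], spent]))

    z = np.linspace(_GRID_LO, _GRID_HI, _GRID_N)
    h = z[1] - z[0]
    trap = np.full(z.size, h)
    trap[0] = trap[-1] = h / 2.0

    bounds: list[float] = []
    density = norm.pdf(z)  # density of Z_1 at look 1
    for k in range(fr.size):
        if k == 0:
            c = float(ndtri(1.0 - increments[0]))
        else:
            # upper-tail mass of the current (sub-)density, from the top
            def tail(c_val: float) -> float:
                mask = z >= c_val
                out = float((density * trap)[mask].sum())
                # partial cell correction at the left edge of the mask
                idx = np.searchsorted(z, c_val)
                if 0 < idx < z.size:
                    frac = (z[idx] - c_val) / h
                    out += float(density[idx - 1] * trap[idx - 1]) * frac
                return out
            from scipy.optimize import brentq

            c = float(brentq(lambda v: tail(v) - increments[k], _GRID_LO, _GRID_HI, xtol=1e-10))
        bounds.append(c)
        if k < fr.size - 1:
            # propagate the continuation density to the next look:
            # Z_{k+1} = r Z_k + sqrt(1 - r^2) eps, r = sqrt(t_k / t_{k+1})
            r = np.sqrt(fr[k] / fr[k + 1])
            sd = np.sqrt(1.0 - r**2)
            cont = np.where(z < c, density, 0.0)
            kernel = norm.pdf((z[:, None] - r * z[None, :]) / sd) / sd
            density = kernel @ (cont * trap)
    return tuple(bounds)


def comparator_boundaries(alpha: float, info_fractions: tuple[float, ...]) -> tuple[float, ...]:
    """Symmetric boundaries for the two-sided chi-square sequential test.

    The chi-square test rejects in either direction, so the overall
    level ``alpha`` is spent half per side; crossing probabilities are
    computed per side (the reflection term is negligible for OBF-shaped
    boundaries).
    """
    return obf_boundaries(alpha / 2.0, info_fractions)


def comparator_test(
    events_a: int,
    n_a: int,
    events_b: int,
    n_b: int,
    boundary: float,
    stage: int,
    n_stages: int,
) -> Decision:
    """Two-proportion chi-square test against a group sequential boundary.

    The signed z statistic (z > 0 when arm A has the lower event rate)
    is compared in absolute value against the symmetric boundary: its
    square against boundary^2 is the familiar chi-square form.
    Comparator designs stop early only on a significant difference, so a
    non-crossing interim always continues.
    """
    if n_a == 0 or n_b == 0:
        return Decision(
            verdict=Verdict.CONTINUE if stage < n_stages else Verdict.FINAL_NOT_SUPERIOR,
            stage=stage,
            flag="empty_arm",
        )
    pa = events_a / n_a
    pb = events_b / n_b
    pooled = (events_a + events_b) / (n_a + n_b)
    var = pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b)
    zstat = 0.0 if var == 0.0 else (pb - pa) / np.sqrt(var)
    reject = abs(zstat) > boundary
    if stage < n_stages:
        verdict = Verdict.STOP_SUPERIOR if reject else Verdict.CONTINUE
    else:
        verdict = Verdict.FINAL_SUPERIOR if reject else Verdict.FINAL_NOT_SUPERIOR
    return Decision(verdict=verdict, stage=stage, statistic=float(zstat), boundary=float(boundary))
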