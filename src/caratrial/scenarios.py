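"""Probit data-generating model and the built-in simulation scenarios.

The outcome model is a two-arm probit regression on binary patient
covariates.  For a patient with covariate vector ``x`` (augmented to
``x~ = (1, x)``) assigned to arm ``G`` (1 = experimental A, 0 = control B),
the event probability is

    Pr(Y = 1 | G, x) = Phi(x~' beta + G * x~' gamma)

where ``Phi`` is the standard normal CDF, ``beta`` collects the intercept
and covariate main (prognostic) effects and ``gamma`` collects the
treatment main effect and treatment-by-covariate (predictive)
interactions.  ``Y = 1`` is an event (a failure, e.g. an advanced
cancer at screening); smaller is better.

Twenty built-in scenarios cover the null configurations (``gamma = 0``,
scenarios 1-9) and alternatives with prognostic and/or predictive
covariate effects (scenarios 10-20).  Covariates are independent
Bernoulli(0.5) by default, giving four equiprobable subgroups for d = 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "RegressionParams",
    "Scenario",
    "response_probability",
    "scenario_table",
    "get_scenario",
    "generate_patient",
    "generate_outcome",
    "subgroup_profiles",
    "profile_weights",
    "true_effect_table",
]


@dataclass(frozen=True)
class RegressionParams:
    """Probit regression coefficients theta = (beta, gamma).

    Parameters
    ----------
    beta
        Intercept and covariate main effects, length d + 1.
    gamma
        Treatment main effect and treatment-covariate interactions,
        length d + 1.
    """

    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)
        if beta.ndim != 1 or gamma.ndim != 1:
            raise ValueError("beta and gamma must be 1-d vectors")
        if beta.shape != gamma.shape:
            raise ValueError(
                f"beta (length {beta.size}) and gamma (length {gamma.size}) "
                "must have equal length"
            )
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(gamma))):
            raise ValueError("all coefficients must be finite")

    @property
    def d(self) -> int:
        """Number of covariates."""
        return self.beta.size - 1

    @property
    def vector(self) -> np.ndarray:
        """Concatenated coefficient vector (beta, gamma) of length 2(d+1)."""
        return np.concatenate([self.beta, self.gamma])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "RegressionParams":
        theta = np.asarray(theta, dtype=float)
        if theta.size % 2:
            raise ValueError("coefficient vector must have even length")
        half = theta.size // 2
        return cls(beta=theta[:half], gamma=theta[half:])


@dataclass(frozen=True)
class Scenario:
    """A simulation scenario: true coefficients plus the covariate law."""

    id: int
    params: RegressionParams
    covariate_dist: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))

    def __post_init__(self) -> None:
        p = np.atleast_1d(np.asarray(self.covariate_dist, dtype=float))
        object.__setattr__(self, "covariate_dist", p)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("covariate success probabilities must lie in [0, 1]")
        if p.size != self.params.d:
            raise ValueError("covariate_dist length must equal number of covariates")

    @property
    def is_null(self) -> bool:
        """True when gamma = 0, i.e. the two arms are exchangeable."""
        return bool(np.all(self.params.gamma == 0))


def _augment(profile: np.ndarray) -> np.ndarray:
    """Prepend the intercept column: x -> x~ = (1, x)."""
    x = np.atleast_2d(np.asarray(profile, dtype=float))
    return np.hstack([np.ones((x.shape[0], 1)), x])


def response_probability(params: RegressionParams, arm, profile) -> np.ndarray | float:
    """Event probability Phi(x~' beta + G x~' gamma).

    ``arm`` may be a scalar 0/1 or a vector matched to the rows of
    ``profile``; ``profile`` may be a single covariate vector or a matrix
    with one row per patient.  Returns a scalar for a single
    (arm, profile) pair, otherwise an array.
    """
    x = np.asarray(profile, dtype=float)
    scalar = x.ndim == 1 and np.ndim(arm) == 0
    xt = _augment(x)
    if xt.shape[1] != params.d + 1:
        raise ValueError(
            f"profile has {xt.shape[1] - 1} covariates, model expects {params.d}"
        )
    g = np.asarray(arm, dtype=float)
    eta = xt @ params.beta + g * (xt @ params.gamma)
    p = ndtr(eta)
    return float(p[0]) if scalar else p


def scenario_table() -> list[Scenario]:
    """The 20 built-in scenarios (independent Bernoulli(0.5) covariates)."""
    with resources.files("caratrial.data").joinpath("scenarios.csv").open() as fh:
        table = pd.read_csv(fh)
    out = []
    for row in table.itertuples(index=False):
        params = RegressionParams(
            beta=np.array([row.beta0, row.beta1, row.beta2]),
            gamma=np.array([row.gamma0, row.gamma1, row.gamma2]),
        )
        out.append(Scenario(id=int(row.sc), params=params))
    return out


def get_scenario(scenario_id: int) -> Scenario:
    """Look up one built-in scenario by its 1-based id."""
    for sc in scenario_table():
        if sc.id == scenario_id:
            return sc
    raise KeyError(f"no built-in scenario with id {scenario_id}")


def generate_patient(
    covariate_dist, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw covariate profiles, each coordinate independent Bernoulli(p_j).

    Returns a (d,) vector when ``size`` is None, else a (size, d) matrix.
    """
    p = np.atleast_1d(np.asarray(covariate_dist, dtype=float))
    n = 1 if size is None else size
    x = (rng.random((n, p.size)) < p).astype(np.int64)
    return x[0] if size is None else x


def generate_outcome(
    params: RegressionParams, arm, profile, rng: np.random.Generator
) -> np.ndarray | int:
    """Draw Y ~ Bernoulli(response_probability); Y = 1 is an event."""
    prob = response_probability(params, arm, profile)
    if np.ndim(prob) == 0:
        return int(rng.random() < prob)
    return (rng.random(np.shape(prob)) < prob).astype(np.int64)


def subgroup_profiles(d: int = 2) -> list[tuple[int, ...]]:
    """All 2^d binary covariate profiles, ordered (1,..,1) down to (0,..,0)."""
    return list(itertools.product((1, 0), repeat=d))


def profile_weights(covariate_dist) -> dict[tuple[int, ...], float]:
    """Population prevalence of each covariate profile under independence."""
    p = np.atleast_1d(np.asarray(covariate_dist, dtype=float))
    weights = {}
    for profile in subgroup_profiles(p.size):
        x = np.asarray(profile)
        weights[profile] = float(np.prod(np.where(x == 1, p, 1.0 - p)))
    return weights


def true_effect_table(scenario: Scenario) -> pd.DataFrame:
    """Analytic per-subgroup and overall event rates (pA, pB).

    The overall row is the prevalence-weighted average of the subgroup
    rates under the scenario's covariate distribution (equal weights 0.25
    for independent Bernoulli(0.5) covariates).
    """
    weights = profile_weights(scenario.covariate_dist)
    rows = []
    overall = {"pA": 0.0, "pB": 0.0}
    for profile, w in weights.items():
        x = np.asarray(profile, dtype=float)
        pa = response_probability(scenario.params, 1, x)
        pb = response_probability(scenario.params, 0, x)
        rows.append({"subgroup": str(profile), "pA": pa, "pB": pb, "weight": w})
        overall["pA"] += w * pa
        overall["pB"] += w * pb
    out = pd.DataFrame(
        [{"subgroup": "overall", **overall, "weight": 1.0}] + rows
    )
    return out.set_index("subgroup")
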