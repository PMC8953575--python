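"""Bayesian probit regression for accumulating trial data.

The regression of the binary event indicator on covariates and arm uses
the design row ``w = (x~, G * x~)`` so that the linear predictor is
``x~' beta + G x~' gamma``.  The prior on theta = (beta, gamma) is an
independent normal centred at the maximum-likelihood estimate with a
moderate diagonal variance (4 by default), which anchors the posterior
without being vague.  Posterior sampling uses truncated-normal data
augmentation (Albert-Chib): the latent variable z_i ~ N(w_i' theta, 1)
with sign fixed by y_i makes the conditional for theta exactly normal,
so the Gibbs sampler targets the posterior without any tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr, ndtri
import statsmodels.api as sm

from .scenarios import RegressionParams

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "PatientRecord",
    "PatientData",
    "MLEFit",
    "fit_mle",
    "default_prior",
    "sample_posterior",
    "posterior_prob_benefit",
    "posterior_mean_rates",
]

DEFAULT_PRIOR_VARIANCE = 4.0
RIDGE_PENALTY = 1.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal prior on theta = (beta, gamma)."""

    mean: np.ndarray
    variance_diag: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        var = np.asarray(self.variance_diag, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "variance_diag", var)
        if mean.shape != var.shape:
            raise ValueError("prior mean and variance must have equal length")
        if np.any(var <= 0):
            raise ValueError("prior variances must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled patient: covariates, arm, outcome and cohort index."""

    profile: tuple[int, ...]
    arm: int
    outcome: int
    cohort: int


@dataclass
class PatientData:
    """Column-oriented accumulating trial data.

    Equivalent to a list of :class:`PatientRecord` but stored as arrays,
    which is what the likelihood computations want.
    """

    x: np.ndarray  # (n, d) binary covariates
    arm: np.ndarray  # (n,) 0/1
    y: np.ndarray  # (n,) 0/1
    cohort: np.ndarray  # (n,) 1-based cohort index

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x))
        self.arm = np.asarray(self.arm)
        self.y = np.asarray(self.y)
        self.cohort = np.asarray(self.cohort)

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord]) -> "PatientData":
        records = list(records)
        if not records:
            raise ValueError("no patient records")
        return cls(
            x=np.array([r.profile for r in records]),
            arm=np.array([r.arm for r in records]),
            y=np.array([r.outcome for r in records]),
            cohort=np.array([r.cohort for r in records]),
        )

    def __len__(self) -> int:
        return self.y.size

    @property
    def d(self) -> int:
        return self.x.shape[1]

    def design_matrix(self) -> np.ndarray:
        """Rows (x~, G * x~) matching theta = (beta, gamma)."""
        ones = np.ones((len(self), 1))
        xt = np.hstack([ones, self.x.astype(float)])
        return np.hstack([xt, self.arm[:, None] * xt])


def _as_patient_data(data) -> PatientData:
    if isinstance(data, PatientData):
        return data
    return PatientData.from_records(data)


@dataclass(frozen=True)
class MLEFit:
    params: RegressionParams
    degenerate: bool = False


def _ridge_probit(W: np.ndarray, y: np.ndarray, penalty: float = RIDGE_PENALTY) -> np.ndarray:
    """L2-penalised probit fit; finite for any data, incl. separation."""
    y = np.asarray(y, dtype=float)
    sign = 2.0 * y - 1.0

    def negloglik(theta):
        eta = sign * (W @ theta)
        return -log_ndtr(eta).sum() + 0.5 * penalty * theta @ theta

    def grad(theta):
        eta = sign * (W @ theta)
        # d/d eta log Phi(eta) = phi(eta)/Phi(eta), computed stably
        ratio = np.exp(-0.5 * eta**2 - 0.5 * np.log(2 * np.pi) - log_ndtr(eta))
        return -W.T @ (sign * ratio) + penalty * theta

    res = minimize(negloglik, np.zeros(W.shape[1]), jac=grad, method="BFGS")
    return res.x


def fit_mle(data) -> MLEFit:
    """Maximum-likelihood probit coefficients for the two-arm model.

    Falls back to a ridge-penalised estimate (flagged ``degenerate``)
    when the MLE does not exist or does not converge — single-arm data,
    constant outcomes, perfect separation — so a running simulation
    never aborts on an unlucky interim dataset.
    """
    pdata = _as_patient_data(data)
    if len(pdata) == 0:
        raise ValueError("cannot fit on empty data")
    W = pdata.design_matrix()
    y = pdata.y.astype(float)

    degenerate = len(np.unique(pdata.arm)) < 2 or len(np.unique(pdata.y)) < 2
    theta = None
    if not degenerate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Probit(y, W).fit(disp=0, warn_convergence=False, maxiter=100)
                converged = bool(fit.mle_retvals.get("converged", False))
                ok = converged and np.all(np.isfinite(fit.params))
                ok = ok and np.max(np.abs(fit.params)) < 15.0  # separation guard
                if ok:
                    theta = np.asarray(fit.params)
                else:
                    degenerate = True
            except Exception:
                degenerate = True
    if theta is None:
        theta = _ridge_probit(W, y)
    return MLEFit(params=RegressionParams.from_vector(theta), degenerate=degenerate)


def default_prior(center: RegressionParams, variance: float = DEFAULT_PRIOR_VARIANCE) -> PriorSpec:
    """MLE-centred normal prior with constant diagonal variance."""
    mean = center.vector
    return PriorSpec(mean=mean, variance_diag=np.full(mean.size, float(variance)))


@dataclass(frozen=True)
class PosteriorDraws:
    """Post burn-in posterior sample of theta = (beta, gamma)."""

    draws: np.ndarray  # (M, 2(d+1))
    iterations: int
    burn_in: int
    seed: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "draws", np.atleast_2d(np.asarray(self.draws, dtype=float)))
        if self.draws.shape[0] == 0:
            raise ValueError("posterior must contain at least one draw")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def d(self) -> int:
        return self.draws.shape[1] // 2 - 1

    @property
    def beta_draws(self) -> np.ndarray:
        return self.draws[:, : self.d + 1]

    @property
    def gamma_draws(self) -> np.ndarray:
        return self.draws[:, self.d + 1 :]

    def mean_params(self) -> RegressionParams:
        """Coordinate-wise posterior mean as a coefficient object."""
        return RegressionParams.from_vector(self.draws.mean(axis=0))

    def to_frame(self) -> pd.DataFrame:
        """Draws as a table (one row per draw) for export/diagnostics."""
        d = self.d
        cols = [f"beta{j}" for j in range(d + 1)] + [f"gamma{j}" for j in range(d + 1)]
        return pd.DataFrame(self.draws, columns=cols)


def sample_posterior(
    data,
    prior: PriorSpec,
    iterations: int = 10_000,
    burn_in: int = 5_000,
    seed=None,
) -> PosteriorDraws:
    """Albert-Chib Gibbs sampler for the Bayesian probit posterior.

    Alternates the truncated-normal latent draw z_i | theta, y_i with the
    exact normal conditional theta | z.  With the fixed design matrix the
    conditional covariance of theta is constant, so its Cholesky factor is
    computed once.  Deterministic given ``seed``.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    pdata = _as_patient_data(data)
    W = pdata.design_matrix()
    y = pdata.y.astype(bool)
    n, p = W.shape
    if prior.mean.size != p:
        raise ValueError(f"prior has {prior.mean.size} coordinates, model needs {p}")
    rng = np.random.default_rng(seed)

    prior_prec = 1.0 / prior.variance_diag
    post_prec = W.T @ W + np.diag(prior_prec)
    V = np.linalg.inv(post_prec)
    L = np.linalg.cholesky(V)
    A = V @ W.T  # maps latent z to the conditional mean contribution
    c0 = V @ (prior_prec * prior.mean)

    theta = prior.mean.copy()
    keep = np.empty((iterations - burn_in, p))
    tiny = 1e-12
    for it in range(iterations):
        m = W @ theta
        # P(z <= 0) for z ~ N(m, 1); inverse-CDF truncated draw
        p0 = ndtr(-m)
        u = rng.random(n)
        q = np.where(y, p0 + u * (1.0 - p0), u * p0)
        z = m + ndtri(np.clip(q, tiny, 1.0 - tiny))
        theta = A @ z + c0 + L @ rng.standard_normal(p)
        if it >= burn_in:
            keep[it - burn_in] = theta
    return PosteriorDraws(draws=keep, iterations=iterations, burn_in=burn_in, seed=seed)


def _augmented(profile) -> np.ndarray:
    x = np.asarray(profile, dtype=float).ravel()
    return np.concatenate([[1.0], x])


def posterior_prob_benefit(posterior: PosteriorDraws, profile) -> float:
    """Posterior probability that arm A has the lower event rate at x.

    Monte Carlo estimate of Pr(pA(x) < pB(x) | data), i.e. the fraction
    of draws with x~' gamma < 0 (strict; draws exactly at zero count as
    not benefiting).
    """
    xt = _augmented(profile)
    if xt.size != posterior.d + 1:
        raise ValueError("profile dimension does not match posterior")
    return float(np.mean(posterior.gamma_draws @ xt < 0.0))


def posterior_mean_rates(posterior: PosteriorDraws, profile) -> tuple[float, float]:
    """Plug-in event rates (pA, pB) at the posterior-mean coefficients."""
    xt = _augmented(profile)
    mean = posterior.mean_params()
    pa = float(ndtr(xt @ mean.beta + xt @ mean.gamma))
    pb = float(ndtr(xt @ mean.beta))
    return pa, pb
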