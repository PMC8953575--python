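"""Treatment allocation rules.

Four rules cover the randomization schemes compared in the simulation
study:

* ``prob_trad`` — fixed 1:1 randomization.
* ``prob_rar`` — Rosenberger-style response-adaptive randomization on
  the pooled per-arm success (non-event) proportions, ignoring
  covariates: allocate to A with probability sqrt(qA)/(sqrt(qA)+sqrt(qB)),
  the failure-minimising allocation for binary outcomes.
* ``prob_cara1`` — personalized randomization from the posterior
  probability p(x) that A benefits a patient with covariates x:
  p(x) / (p(x) + 1 - p(x)).  The denominator is identically one, so the
  rule equals p(x); it is written out so the published form is what runs.
* ``prob_cara2`` — covariate-adjusted randomization proportional to the
  estimated non-event rates: (1 - pA(x)) / ((1 - pA(x)) + (1 - pB(x))).

All probabilities refer to arm A (the experimental arm).
"""

from __future__ import annotations

import enum
import math

__all__ = [
    "Design",
    "RAR_CLIP",
    "prob_trad",
    "prob_rar",
    "prob_cara1",
    "prob_cara2",
]


class Design(str, enum.Enum):
    """The five trial designs the engine can run."""

    TRAD = "trad"
    RAR = "rar"
    CARA1 = "cara1"
    CARA2 = "cara2"
    BACARA = "bacara"


# Per-arm success proportions are clipped away from 0 and 1 before the
# square-root rule: a small-cohort guard against 0/0 and absorbing
# allocation that leaves the asymptotics untouched.
RAR_CLIP = (0.05, 0.95)


def prob_trad() -> float:
    """Fixed equal randomization: always 1/2."""
    return 0.5


def prob_rar(
    success_rate_a: float,
    success_rate_b: float,
    clip: tuple[float, float] = RAR_CLIP,
) -> float:
    """Square-root allocation on the observed per-arm success rates."""
    lo, hi = clip
    qa = min(max(float(success_rate_a), lo), hi)
    qb = min(max(float(success_rate_b), lo), hi)
    if qa == 0.0 and qb == 0.0:
        return 0.5
    ra, rb = math.sqrt(qa), math.sqrt(qb)
    return ra / (ra + rb)


def prob_cara1(p_benefit: float) -> float:
    """Personalized allocation probability pi_A(x) from p(x) = Pr(pA < pB | data)."""
    p = float(p_benefit)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_benefit must lie in [0, 1]")
    return p / (p + (1.0 - p))


def prob_cara2(pa_hat: float, pb_hat: float) -> float:
    """Allocation proportional to the estimated non-event probabilities."""
    pa, pb = float(pa_hat), float(pb_hat)
    if not (0.0 <= pa <= 1.0 and 0.0 <= pb <= 1.0):
        raise ValueError("estimated rates must lie in [0, 1]")
    qa, qb = 1.0 - pa, 1.0 - pb
    if qa + qb == 0.0:
        return 0.5
    return qa / (qa + qb)
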