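"""Two-state Markov chain of single-CpG methylation dynamics.

State 0 is unmethylated, state 1 methylated. Per-step switch
probabilities are ``p`` (0 -> 1) and ``q`` (1 -> 0). The module exposes
the transition matrix, the exact probability of being methylated after
``t`` steps when starting unmethylated (closed form and recurrence), the
steady state, and the small-rate linear approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoStateRates",
    "transition_matrix",
    "prob_methylated_closed_form",
    "prob_methylated_recurrence",
    "linear_approximation",
    "steady_state",
]


@dataclass(frozen=True)
class TwoStateRates:
    """Per-step switch probabilities of the two-state chain.

    Parameters
    ----------
    p : float
        Probability of a 0 -> 1 (methylation gain) switch per step.
    q : float
        Probability of a 1 -> 0 (methylation loss) switch per step.
    """

    p: float
    q: float

    def __post_init__(self) -> None:
        for name, value in (("p", self.p), ("q", self.q)):
            if not (0.0 <= value <= 1.0) or not math.isfinite(value):
                raise ValueError(f"rate {name}={value!r} must lie in [0, 1]")


def transition_matrix(rates: TwoStateRates) -> np.ndarray:
    """Return the 2x2 row-stochastic transition matrix [[1-p, p], [q, 1-q]]."""
    p, q = rates.p, rates.q
    return np.array([[1.0 - p, p], [q, 1.0 - q]])


def _validate_steps(t: int) -> int:
    if t != int(t) or t < 0:
        raise ValueError(f"step count t={t!r} must be a nonnegative integer")
    return int(t)


def prob_methylated_closed_form(rates: TwoStateRates, t: int) -> float:
    """Probability of the methylated state after ``t`` steps from state 0.

    Evaluates ``p/(p+q) * (1 - (1-p-q)**t)`` exactly; 0 at ``t == 0`` and
    converging to the steady state ``p/(p+q)`` as ``t`` grows. The
    degenerate chain ``p == q == 0`` stays absorbed in state 0.
    """
    t = _validate_steps(t)
    p, q = rates.p, rates.q
    if t == 0 or p == 0.0:
        return 0.0
    s = p + q
    r = 1.0 - s
    # exp-log path avoids overflow/underflow of the direct power for
    # large t; only valid for a strictly positive base.
    if r > 0.0:
        rt = math.exp(t * math.log(r))
    else:
        rt = r**t
    return (p / s) * (1.0 - rt)


def prob_methylated_recurrence(rates: TwoStateRates, t: int) -> float:
    """Same quantity as the closed form, by iterating
    ``P01 <- p + (1 - p - q) * P01`` from ``P01 = 0``."""
    t = _validate_steps(t)
    p, q = rates.p, rates.q
    shrink = 1.0 - p - q
    prob = 0.0
    for _ in range(t):
        prob = p + shrink * prob
    return prob


def linear_approximation(rates: TwoStateRates, t: int) -> tuple[float, float]:
    """Small-rate linear approximation ``P01(t) ~= p*t``.

    Returns ``(approx, abs_error)`` where ``abs_error`` is the absolute
    deviation from the exact closed form. The approximation is accurate
    only in the linear regime (tiny ``p``, ``q`` and ``p*t`` well below
    the steady state); outside it the error can exceed 1.
    """
    t = _validate_steps(t)
    approx = rates.p * t
    exact = prob_methylated_closed_form(rates, t)
    return approx, abs(exact - approx)


def steady_state(rates: TwoStateRates) -> tuple[float, float]:
    """Stationary distribution ``(pi0, pi1) = (q, p) / (p + q)``."""
    p, q = rates.p, rates.q
    s = p + q
    if s == 0.0:
        raise ValueError("steady state undefined for p = q = 0")
    return q / s, p / s
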