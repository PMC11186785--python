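"""Population-level stochastic DNAm-accrual engine.

Each CpG ``c`` is altered per time step with probability
``p_c = 1 - exp(-gamma * |effect_c|)``. When altered, a half-normal
deviate ``|N(0, sigma)|`` signed by the direction of the CpG's effect is
added to the beta-value in inverse-normal-quantile space, which keeps
betas strictly inside (0, 1) and reproduces the heteroscedasticity of
beta-values (changes shrink toward the 0/1 boundaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "alteration_probability",
    "beta_to_quantile",
    "quantile_to_beta",
    "step_count",
    "step_quantiles",
    "simulate_sample",
    "simulate_trajectory",
    "simulate_end_state_batch",
]


@dataclass(frozen=True)
class SimParams:
    """Tunables of the stochastic accrual simulator.

    gamma
        Global alteration-rate: scales the per-step probability that a
        CpG's value changes at all.
    sigma
        Scale of the quantile-space half-normal deviate added on each
        alteration.
    steps_per_year
        Time discretization anchor (default 35 steps per year).
    base_age
        Age at which simulation starts from the ground state.
    clip_eps
        Betas are clipped to ``[clip_eps, 1 - clip_eps]`` before the
        inverse-normal transform.
    """

    gamma: float
    sigma: float
    steps_per_year: int = 35
    base_age: float = 45.0
    clip_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma={self.gamma} must be >= 0")
        if self.sigma < 0:
            raise ValueError(f"sigma={self.sigma} must be >= 0")
        if self.steps_per_year < 1:
            raise ValueError("steps_per_year must be >= 1")
        if not (0 < self.clip_eps < 0.5):
            raise ValueError("clip_eps must lie in (0, 0.5)")


def alteration_probability(effect_size, gamma: float):
    """Per-step probability ``1 - exp(-gamma * |effect_size|)`` of a change.

    Vectorized over ``effect_size``; 0 exactly when either ``gamma`` or
    the effect size is 0, saturating toward 1 for large products.
    """
    if gamma < 0:
        raise ValueError(f"gamma={gamma} must be >= 0")
    return -np.expm1(-gamma * np.abs(effect_size))


def beta_to_quantile(beta, eps: float = 1e-6):
    """Inverse standard-normal CDF of betas clipped to ``[eps, 1-eps]``.

    Logs the number of values that had to be clipped.
    """
    beta = np.asarray(beta, dtype=float)
    n_clipped = int(np.sum((beta < eps) | (beta > 1.0 - eps)))
    if n_clipped:
        logger.debug("clipped %d beta-values to [%g, %g]", n_clipped, eps, 1 - eps)
    return ndtri(np.clip(beta, eps, 1.0 - eps))


def quantile_to_beta(x, eps: float = 0.0):
    """Standard-normal CDF, mapping quantile space back to (0, 1).

    With ``eps > 0`` the result is clipped to ``[eps, 1 - eps]``, which
    guards against float underflow to exactly 0/1 at extreme quantiles.
    """
    beta = ndtr(np.asarray(x, dtype=float))
    if eps:
        beta = np.clip(beta, eps, 1.0 - eps)
    return beta


def step_count(params: SimParams, age: float) -> int:
    """Number of simulation steps from ``base_age`` to ``age``.

    Fractional ages are supported by rounding
    ``steps_per_year * (age - base_age)`` to the nearest integer.
    """
    if age < params.base_age:
        raise ValueError(
            f"age {age} below simulation base age {params.base_age}"
        )
    return int(round(params.steps_per_year * (age - params.base_age)))


def _effect_arrays(effects: pd.DataFrame, gamma: float):
    eff = effects["effect_size"].to_numpy(dtype=float)
    return alteration_probability(eff, gamma), np.sign(eff)


def step_quantiles(
    x: np.ndarray,
    alter_prob: np.ndarray,
    sign: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One simulation step applied to quantile-space profile(s) ``x``.

    ``x`` may be 1-D (one profile) or 2-D (replicates x CpGs); the
    alteration probabilities and signs broadcast along the last axis.
    """
    altered = rng.random(x.shape) < alter_prob
    deviates = np.abs(rng.standard_normal(x.shape)) * sigma
    return x + altered * sign * deviates


def simulate_sample(
    ground: np.ndarray,
    effects: pd.DataFrame,
    params: SimParams,
    age: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one sample's beta profile from the ground state to ``age``."""
    n_steps = step_count(params, age)
    p_alter, sign = _effect_arrays(effects, params.gamma)
    x = beta_to_quantile(ground, params.clip_eps)
    for _ in range(n_steps):
        x = step_quantiles(x, p_alter, sign, params.sigma, rng)
    return quantile_to_beta(x, params.clip_eps)


def simulate_trajectory(
    ground: np.ndarray,
    effects: pd.DataFrame,
    params: SimParams,
    age: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Like :func:`simulate_sample` but returns the full path.

    The result has shape ``(n_steps + 1, n_cpgs)``; row 0 is the
    (clip/transform round-tripped) ground state, so the number of steps
    the engine executed is ``result.shape[0] - 1``.
    """
    n_steps = step_count(params, age)
    p_alter, sign = _effect_arrays(effects, params.gamma)
    x = beta_to_quantile(ground, params.clip_eps)
    path = np.empty((n_steps + 1, x.size))
    path[0] = quantile_to_beta(x, params.clip_eps)
    for i in range(n_steps):
        x = step_quantiles(x, p_alter, sign, params.sigma, rng)
        path[i + 1] = quantile_to_beta(x, params.clip_eps)
    return path


def simulate_end_state_batch(
    ground: np.ndarray,
    effects: pd.DataFrame,
    params: SimParams,
    n_steps: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """End-state betas of ``n_reps`` independent runs of ``n_steps`` steps.

    All replicates start from the same ground profile and advance in
    lock-step, which vectorizes the inner loop; statistically identical
    to ``n_reps`` calls of :func:`simulate_sample`. Returns shape
    ``(n_reps, n_cpgs)``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    p_alter, sign = _effect_arrays(effects, params.gamma)
    x0 = beta_to_quantile(ground, params.clip_eps)
    x = np.tile(x0, (n_reps, 1))
    for _ in range(n_steps):
        x = step_quantiles(x, p_alter, sign, params.sigma, rng)
    return quantile_to_beta(x, params.clip_eps)
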