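"""Synthetic fixtures: reference panels, aging cohorts, cell fractions.

Everything downstream of real methylation arrays can be exercised with
the generators here: young/old sorted-cell reference panels with a known
generative truth, "real-aging" whole-blood-like cohorts that mix the
stochastic accrual process with configurable nonstochastic components
(covariate offsets, cell-composition shifts), and row-stochastic
cell-fraction matrices.

Beta-valued noise and offsets are applied in inverse-normal-quantile
space by default, so values stay inside (0, 1) and the variance shrinks
toward the boundaries, mimicking the heteroscedasticity of real
beta-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stochclock.effects import effects_from_arrays
from stochclock.simulate import (
    SimParams,
    beta_to_quantile,
    quantile_to_beta,
    simulate_sample,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePanel",
    "NonstochasticEffect",
    "CellShift",
    "AgingCohortSpec",
    "make_reference_panel",
    "make_aging_cohort",
    "make_cell_fractions",
]


@dataclass
class ReferencePanel:
    """Young/old reference groups plus the generative truth."""

    young: pd.DataFrame
    old: pd.DataFrame
    true_effects: pd.DataFrame
    young_ages: np.ndarray
    old_ages: np.ndarray


@dataclass
class NonstochasticEffect:
    """A covariate-scaled deterministic offset added to each sample.

    ``offsets`` is a per-CpG vector, ``values`` the per-sample covariate
    (e.g. 0/1 for sex). ``space`` chooses whether offsets act on normal
    quantiles (default; bounded by construction) or directly on betas
    (clamped, clamp events logged).
    """

    name: str
    offsets: np.ndarray
    values: np.ndarray
    space: str = "quantile"

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.space not in ("quantile", "beta"):
            raise ValueError(f"unknown offset space {self.space!r}")


@dataclass
class CellShift:
    """Group-wise cell-composition shift for bulk-mixture cohorts.

    Each of the ``k`` cell types has its own methylation profile (type 0
    is the simulated profile itself, the others are fixed quantile-space
    offsets of it); a sample's bulk beta is the fraction-weighted convex
    mixture. Shifting fractions between groups therefore moves bulk
    betas without touching the underlying aging process.
    """

    group_labels: np.ndarray
    deltas: dict
    k: int = 12
    base: np.ndarray | None = None
    fraction_noise: float = 0.01
    profile_scale: float = 0.3
    profile_seed: int = 0

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels)


@dataclass
class AgingCohortSpec:
    """Recipe for a synthetic 'real-aging' cohort.

    If ``ages`` is given it fixes each sample's age (length must equal
    ``n_samples``); otherwise integer ages are drawn uniformly from
    ``age_range``. Explicit ages let callers build age-dependent
    covariates for the nonstochastic components.
    """

    n_samples: int
    age_range: tuple[float, float]
    params: SimParams
    nonstochastic_effects: list = field(default_factory=list)
    cell_shift: CellShift | None = None
    seed: int = 0
    ages: np.ndarray | None = None


def make_reference_panel(
    n_cpgs: int,
    n_young: int,
    n_old: int,
    effect_sd: float = 0.02,
    frac_hyper: float = 0.5,
    seed: int = 0,
    noise_sd: float = 0.05,
    max_abs_effect: float = 0.05,
    young_age: float = 45.0,
) -> ReferencePanel:
    """Generate a young/old sorted-cell reference panel.

    Ground states are drawn bimodally (beta-like modes near 0.1 and 0.9
    plus 20% intermediate uniform mass). Effect magnitudes are
    half-normal with scale ``effect_sd``, capped at ``max_abs_effect``,
    hypermethylating with probability ``frac_hyper``. Old-group means
    are ground + effect; per-sample noise is added in quantile space
    with scale ``noise_sd``.
    """
    if n_cpgs < 2:
        raise ValueError("n_cpgs must be >= 2")
    if n_young < 2 or n_old < 2:
        raise ValueError("need at least 2 samples per group")
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if not (0 <= frac_hyper <= 1):
        raise ValueError("frac_hyper must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    component = rng.choice(3, size=n_cpgs, p=[0.4, 0.4, 0.2])
    ground = np.where(
        component == 0,
        rng.beta(2.0, 18.0, size=n_cpgs),
        np.where(
            component == 1,
            rng.beta(18.0, 2.0, size=n_cpgs),
            rng.uniform(0.15, 0.85, size=n_cpgs),
        ),
    )

    if effect_sd == 0:
        effect = np.zeros(n_cpgs)
    else:
        magnitude = np.minimum(
            np.abs(rng.normal(0.0, effect_sd, size=n_cpgs)), max_abs_effect
        )
        sign = np.where(rng.random(n_cpgs) < frac_hyper, 1.0, -1.0)
        effect = sign * magnitude
    raw_old = ground + effect
    censored = np.mean((raw_old < 0) | (raw_old > 1))
    if censored > 0.10:
        raise ValueError(
            f"effect_sd={effect_sd} censors {censored:.0%} of old-state "
            "values at the [0, 1] boundary (limit 10%)"
        )
    old_state = np.clip(raw_old, 0.0, 1.0)

    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(n_cpgs)], name="cpg_id")

    def _group(mean_beta: np.ndarray, n: int, prefix: str) -> pd.DataFrame:
        x0 = beta_to_quantile(mean_beta)
        samples = quantile_to_beta(
            x0[:, None] + rng.normal(0.0, noise_sd, size=(n_cpgs, n))
        )
        cols = [f"{prefix}_{i:03d}" for i in range(n)]
        return pd.DataFrame(samples, index=cpg_ids, columns=cols)

    young = _group(ground, n_young, "young")
    old = _group(old_state, n_old, "old")
    return ReferencePanel(
        young=young,
        old=old,
        true_effects=effects_from_arrays(cpg_ids, ground, old_state),
        young_ages=np.full(n_young, float(young_age)),
        old_ages=rng.choice([81.0, 82.0, 83.0], size=n_old),
    )


def make_cell_fractions(
    n_samples: int,
    k: int = 12,
    base: np.ndarray | None = None,
    group_deltas: dict | None = None,
    group_labels=None,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Row-stochastic cell-fraction matrix with optional group shifts.

    Rows are ``base`` (default uniform) plus the group's delta plus
    optional Gaussian jitter, clipped at 0 and renormalized to sum to 1.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if base is None:
        base = np.full(k, 1.0 / k)
    base = np.asarray(base, dtype=float)
    if base.size != k:
        raise ValueError(f"base must have length k={k}")
    if np.any(base < 0) or abs(base.sum() - 1.0) > 1e-8:
        raise ValueError("base must lie on the simplex")
    if group_deltas:
        if group_labels is None:
            raise ValueError("group_deltas given without group_labels")
        group_labels = np.asarray(group_labels)
        if group_labels.size != n_samples:
            raise ValueError("group_labels length must equal n_samples")
    rng = np.random.default_rng(seed)

    rows = np.tile(base, (n_samples, 1))
    if group_deltas:
        for label, delta in group_deltas.items():
            delta = np.asarray(delta, dtype=float)
            if delta.size != k:
                raise ValueError(f"delta for group {label!r} has wrong length")
            rows[group_labels == label] += delta
    if noise > 0:
        rows += rng.normal(0.0, noise, size=rows.shape)
    rows = np.clip(rows, 0.0, None)
    sums = rows.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("a fraction row collapsed to all zeros")
    rows /= sums[:, None]
    return pd.DataFrame(
        rows,
        columns=[f"frac_{j + 1}" for j in range(k)],
        index=[f"s{i:04d}" for i in range(n_samples)],
    )


def make_aging_cohort(
    panel: ReferencePanel, spec: AgingCohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realize a cohort mixing stochastic accrual with nonstochastic signal.

    Each sample starts from a randomly drawn young-panel profile, runs
    the stochastic simulator to its (integer, uniform) age, then
    receives any configured covariate offsets and, if a cell shift is
    configured, is turned into a fraction-weighted bulk mixture.

    Returns ``(betas, metadata)``; metadata carries age, covariates,
    group labels and the fraction matrix when applicable.
    """
    lo, hi = spec.age_range
    if lo < spec.params.base_age:
        raise ValueError(
            f"cohort minimum age {lo} below simulator base age "
            f"{spec.params.base_age}"
        )
    if hi < lo:
        raise ValueError("age_range must be increasing")
    for eff in spec.nonstochastic_effects:
        if eff.values.size != spec.n_samples:
            raise ValueError(
                f"covariate {eff.name!r} has {eff.values.size} values for "
                f"{spec.n_samples} samples"
            )
        if eff.offsets.size != len(panel.true_effects):
            raise ValueError(f"offset vector of {eff.name!r} has wrong length")

    master = np.random.SeedSequence(spec.seed)
    age_rng = np.random.default_rng(master.spawn(1)[0])
    sample_seeds = master.spawn(spec.n_samples + 2)[2:]
    if spec.ages is not None:
        ages = np.asarray(spec.ages, dtype=float)
        if ages.size != spec.n_samples:
            raise ValueError("explicit ages length must equal n_samples")
        if np.any(ages < spec.params.base_age):
            raise ValueError("explicit ages below simulator base age")
    else:
        ages = age_rng.integers(
            int(lo), int(hi) + 1, size=spec.n_samples
        ).astype(float)

    effects = panel.true_effects
    pool = panel.young.loc[effects.index].to_numpy(dtype=float)
    eps = spec.params.clip_eps

    fractions = None
    type_offsets = None
    if spec.cell_shift is not None:
        cs = spec.cell_shift
        if cs.group_labels.size != spec.n_samples:
            raise ValueError("cell_shift group labels must match n_samples")
        fractions = make_cell_fractions(
            spec.n_samples,
            k=cs.k,
            base=cs.base,
            group_deltas=cs.deltas,
            group_labels=cs.group_labels,
            noise=cs.fraction_noise,
            seed=np.random.default_rng(master.spawn(2)[1]).integers(2**31),
        )
        # per-cell-type quantile offsets are properties of the cell
        # types, seeded independently of the cohort so repeated cohorts
        # share them; type 0 is the simulated profile itself
        prof_rng = np.random.default_rng(cs.profile_seed)
        type_offsets = prof_rng.normal(
            0.0, cs.profile_scale, size=(cs.k, len(effects))
        )
        type_offsets[0] = 0.0

    n_clamped = 0
    columns = {}
    for i, child in enumerate(sample_seeds):
        rng = np.random.default_rng(child)
        j = int(rng.integers(pool.shape[1]))
        beta = simulate_sample(pool[:, j], effects, spec.params, ages[i], rng)
        x = beta_to_quantile(beta, eps)
        for eff in spec.nonstochastic_effects:
            if eff.space == "quantile":
                x = x + eff.offsets * eff.values[i]
            else:
                shifted = quantile_to_beta(x) + eff.offsets * eff.values[i]
                n_clamped += int(np.sum((shifted < 0) | (shifted > 1)))
                x = beta_to_quantile(np.clip(shifted, 0.0, 1.0), eps)
        if type_offsets is not None:
            mix = quantile_to_beta(x[None, :] + type_offsets)
            beta_out = fractions.iloc[i].to_numpy() @ mix
        else:
            beta_out = quantile_to_beta(x)
        columns[f"s{i:04d}"] = beta_out
    if n_clamped:
        logger.warning("clamped %d beta-values during offset application",
                       n_clamped)

    betas = pd.DataFrame(columns, index=effects.index.copy())
    meta = pd.DataFrame({"sample_id": list(columns), "age": ages})
    for eff in spec.nonstochastic_effects:
        meta[eff.name] = eff.values
    if spec.cell_shift is not None:
        meta["group"] = spec.cell_shift.group_labels
        frac = fractions.reset_index(drop=True)
        meta = pd.concat([meta, frac], axis=1)
    meta = meta.set_index("sample_id")
    return betas, meta
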