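"""Per-CpG ground states, effect sizes and CpG selection rules.

An effect-size table is a :class:`pandas.DataFrame` indexed by CpG id
with columns ``ground_state`` (mean beta over the young group),
``old_state`` (mean beta over the old group) and ``effect_size``
(``old_state - ground_state``, signed). The sign of the effect size
fixes the direction of simulated drift and is frozen at estimation time.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "estimate_effects",
    "reduced_clock_filter",
    "select_top_cpgs",
    "effects_from_arrays",
    "read_effects",
    "write_effects",
]

EFFECT_COLUMNS = ("ground_state", "old_state", "effect_size")


def effects_from_arrays(
    cpg_ids: Sequence[str],
    ground_state: np.ndarray,
    old_state: np.ndarray,
) -> pd.DataFrame:
    """Assemble an effect-size table from per-CpG group means."""
    ground = np.asarray(ground_state, dtype=float)
    old = np.asarray(old_state, dtype=float)
    if not (len(cpg_ids) == ground.size == old.size):
        raise ValueError("cpg_ids, ground_state and old_state lengths differ")
    table = pd.DataFrame(
        {
            "ground_state": ground,
            "old_state": old,
            "effect_size": old - ground,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    _validate_effect_table(table)
    return table


def _validate_effect_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG ids in effect table: {dupes[:5]}")
    for col in ("ground_state", "old_state"):
        vals = table[col].to_numpy()
        if np.any((vals < 0) | (vals > 1)) or np.any(~np.isfinite(vals)):
            bad = table.index[(vals < 0) | (vals > 1) | ~np.isfinite(vals)][0]
            raise ValueError(f"{col} out of [0, 1] at CpG {bad!r}")


def estimate_effects(
    young: pd.DataFrame,
    old: pd.DataFrame,
    cpg_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Estimate ground state, old state and signed effect per CpG.

    ``young`` and ``old`` are beta matrices (CpGs x samples). The ground
    state is the arithmetic mean over young samples, the effect size the
    difference of old and young means. CpGs with a zero effect are kept;
    downstream they simply have alteration probability 0.

    Raises
    ------
    KeyError
        If a requested CpG is missing from either matrix.
    ValueError
        On missing values (imputation is out of scope) or groups with
        fewer than two samples.
    """
    if young.shape[1] < 2 or old.shape[1] < 2:
        raise ValueError("need at least two samples per group")
    if cpg_subset is None:
        cpg_subset = young.index.intersection(old.index, sort=False)
    cpg_subset = pd.Index(cpg_subset)
    for name, mat in (("young", young), ("old", old)):
        missing = cpg_subset.difference(mat.index)
        if len(missing):
            raise KeyError(
                f"CpGs missing from {name} matrix: {missing.tolist()[:5]}"
            )
        sub = mat.loc[cpg_subset]
        if sub.isna().any().any():
            rows = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing values in {name} matrix at CpGs {rows[:5]}"
            )
    return effects_from_arrays(
        cpg_subset,
        young.loc[cpg_subset].mean(axis=1).to_numpy(),
        old.loc[cpg_subset].mean(axis=1).to_numpy(),
    )


def reduced_clock_filter(
    effects_a: pd.DataFrame,
    effects_b: pd.DataFrame,
    max_ground_diff: float = 0.1,
) -> pd.Index:
    """CpGs with similar ground states and concordant drift direction.

    Keeps CpGs whose ground-state betas differ by strictly less than
    ``max_ground_diff`` between the two tables and whose effect signs
    agree and are nonzero in both.
    """
    shared = effects_a.index.intersection(effects_b.index, sort=False)
    if len(shared) == 0:
        raise ValueError("effect tables share no CpGs")
    a = effects_a.loc[shared]
    b = effects_b.loc[shared]
    ground_ok = (
        np.abs(a["ground_state"].to_numpy() - b["ground_state"].to_numpy())
        < max_ground_diff
    )
    sign_a = np.sign(a["effect_size"].to_numpy())
    sign_b = np.sign(b["effect_size"].to_numpy())
    concordant = (sign_a == sign_b) & (sign_a != 0)
    return shared[ground_ok & concordant]


def select_top_cpgs(effects: pd.DataFrame, k: int) -> pd.Index:
    """The ``k`` CpGs with largest absolute effect size.

    Ties are broken by lexicographic CpG id so the selection is
    deterministic.
    """
    if k <= 0:
        raise ValueError(f"k={k} must be positive")
    if k > len(effects):
        raise ValueError(f"k={k} exceeds table size {len(effects)}")
    # sort on (|effect| desc, cpg_id asc) without mutating the input
    tmp = pd.DataFrame(
        {
            "abs_effect": effects["effect_size"].abs().to_numpy(),
            "cpg_id": effects.index.to_numpy(),
        }
    )
    tmp = tmp.sort_values(
        ["abs_effect", "cpg_id"], ascending=[False, True], kind="mergesort"
    )
    return pd.Index(tmp["cpg_id"].to_numpy()[:k], name="cpg_id")


def write_effects(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="cpg_id")


def read_effects(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="cpg_id", comment="#")
    missing = [c for c in EFFECT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"effect table missing columns: {missing}")
    _validate_effect_table(table)
    return table[list(EFFECT_COLUMNS)]
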