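"""Age-acceleration residuals (EAA/IAA) and phenotype association tests.

EAA is the residual of predicted DNAm-age regressed on chronological
age. IAA additionally adjusts for immune-cell composition by including
11 of the 12 cell-type fractions in the regression (only 11 are
independent because the fractions sum to 1; with an intercept the
residuals do not depend on which one is dropped).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["eaa", "iaa", "test_association"]

EXACT_RANKSUM_MAX_N = 50  # combined size below which the exact null is used


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def eaa(dnam_age, age) -> np.ndarray:
    """Extrinsic age acceleration: OLS residuals of DNAm-age on age."""
    dnam_age = np.asarray(dnam_age, dtype=float)
    age = np.asarray(age, dtype=float)
    if dnam_age.shape != age.shape:
        raise ValueError("dnam_age and age differ in length")
    if dnam_age.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(age) == 0:
        raise ValueError("chronological age is constant")
    return _ols_residuals(dnam_age, age[:, None])


def iaa(dnam_age, age, fractions) -> np.ndarray:
    """Intrinsic age acceleration: residuals of DNAm-age on age plus
    cell-type fractions.

    ``fractions`` is an (n_samples x k) row-stochastic matrix (k = 12
    for the immune reference). The fraction with the largest mean is
    dropped to remove the simplex collinearity; residuals are invariant
    to this choice.
    """
    dnam_age = np.asarray(dnam_age, dtype=float)
    age = np.asarray(age, dtype=float)
    frac = (
        fractions.to_numpy(dtype=float)
        if isinstance(fractions, pd.DataFrame)
        else np.asarray(fractions, dtype=float)
    )
    if frac.ndim != 2 or frac.shape[0] != dnam_age.size:
        raise ValueError("fractions must be (n_samples x k)")
    sums = frac.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("fraction rows must sum to 1")
    k = frac.shape[1]
    if dnam_age.size <= k + 1:
        raise ValueError("too few samples for the fraction-adjusted fit")
    drop = int(np.argmax(frac.mean(axis=0)))
    kept = np.delete(frac, drop, axis=1)
    # constant columns (e.g. fractions identical across samples) carry
    # no information and would only add collinearity with the intercept
    varying = np.ptp(kept, axis=0) > 0
    X = np.column_stack([age, kept[:, varying]])
    return _ols_residuals(dnam_age, X)


def test_association(acc, phenotype, kind: str) -> tuple[float, float]:
    """Association between acceleration residuals and a phenotype.

    ``kind`` selects the test:

    - ``"wilcoxon_two_tailed"`` / ``"wilcoxon_one_tailed"``: rank-sum
      test between the two phenotype groups (exact null below a
      combined n of 50, normal approximation with continuity correction
      above). The one-tailed alternative is that the higher-coded group
      has larger residuals.
    - ``"ordinal_regression"``: linear regression of the residuals on
      the numeric phenotype codes; returns the slope and its two-tailed
      t-test p.

    Returns ``(statistic, p_value)``.
    """
    acc = np.asarray(acc, dtype=float)
    phen = np.asarray(phenotype)
    if acc.shape != phen.shape:
        raise ValueError("acc and phenotype differ in length")

    if kind == "ordinal_regression":
        codes = phen.astype(float)
        if np.ptp(codes) == 0:
            raise ValueError("phenotype is constant")
        fit = stats.linregress(codes, acc)
        return float(fit.slope), float(fit.pvalue)

    if kind not in ("wilcoxon_two_tailed", "wilcoxon_one_tailed"):
        raise ValueError(f"unknown test kind {kind!r}")
    groups = np.unique(phen)
    if len(groups) != 2:
        raise ValueError(
            f"rank-sum test needs exactly 2 groups, got {len(groups)}"
        )
    lo = acc[phen == groups[0]]
    hi = acc[phen == groups[1]]
    if min(len(lo), len(hi)) < 2:
        raise ValueError("need >= 2 samples per group")
    n = len(lo) + len(hi)
    has_ties = len(np.unique(acc)) < n
    method = (
        "exact" if (n < EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    )
    alternative = "two-sided" if kind == "wilcoxon_two_tailed" else "greater"
    res = stats.mannwhitneyu(hi, lo, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
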