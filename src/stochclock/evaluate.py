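"""Clock evaluation metrics, the RR2 ratio and cross-cohort meta-analysis.

R-squared here is the squared Pearson correlation of predicted versus
true age (not a regression R-squared), so the ratio of two clocks' R2
values on the same cohort cancels cohort-specific calibration biases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EvalResult",
    "RR2Record",
    "evaluate",
    "rr2",
    "rr2_vs_unexplained",
    "meta_compare",
]


@dataclass
class EvalResult:
    """Accuracy metrics of one clock on one cohort."""

    mae: float
    median_ae: float
    pearson_r: float
    r2: float
    p_value: float
    n: int

    @property
    def degenerate(self) -> bool:
        """True when the correlation was undefined (constant input)."""
        return not np.isfinite(self.pearson_r)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "median_ae": self.median_ae,
            "pearson_r": self.pearson_r,
            "r2": self.r2,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass
class RR2Record:
    """Ratio of R2 values of a stochastic clock to its original clock."""

    cohort: str
    clock_pair: str
    rr2: float
    n: int
    r2_stochastic: float
    r2_original: float


def evaluate(predicted, true) -> EvalResult:
    """MAE, median AE, Pearson R (with two-tailed p) and R2.

    Constant predictions leave the correlation undefined; the result
    then carries NaN correlation fields but still reports the MAE.
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true ages differ in length")
    n = predicted.size
    if n < 3:
        raise ValueError("need at least 3 samples to evaluate")
    if np.ptp(true) == 0:
        raise ValueError("true ages are constant")
    err = predicted - true
    mae = float(np.mean(np.abs(err)))
    med = float(np.median(np.abs(err)))
    if np.ptp(predicted) == 0:
        return EvalResult(mae, med, float("nan"), float("nan"), float("nan"), n)
    r, p = stats.pearsonr(predicted, true)
    return EvalResult(mae, med, float(r), float(r) ** 2, float(p), n)


def rr2(
    stoc: EvalResult,
    orig: EvalResult,
    cohort: str = "",
    clock_pair: str = "",
) -> RR2Record:
    """RR2 = R2(stochastic clock) / R2(original clock) on one cohort."""
    if not np.isfinite(orig.r2) or orig.r2 == 0:
        raise ZeroDivisionError("original clock R2 is zero or undefined")
    if not np.isfinite(stoc.r2):
        raise ValueError("stochastic clock R2 is undefined")
    ratio = stoc.r2 / orig.r2
    if ratio > 1:
        warnings.warn(
            f"RR2 = {ratio:.3f} exceeds 1 (stochastic clock outperforms "
            "the original on this cohort)",
            stacklevel=2,
        )
    return RR2Record(
        cohort=cohort,
        clock_pair=clock_pair,
        rr2=float(ratio),
        n=min(stoc.n, orig.n),
        r2_stochastic=stoc.r2,
        r2_original=orig.r2,
    )


def rr2_vs_unexplained(records: list[RR2Record]):
    """Diagnostic against the 'unexplained variation' hypothesis.

    For each record returns the pair ``(1/R2_original - 1, rr2)`` plus
    the Pearson correlation of the pairs. Under the alternative
    hypothesis that stochastic clocks capture the variation a clock does
    NOT explain, rr2 would be proportional to ``1/R2 - 1``.
    """
    pairs = []
    for rec in records:
        if rec.r2_original == 0:
            warnings.warn(
                f"record {rec.cohort!r} excluded: original R2 is zero",
                stacklevel=2,
            )
            continue
        pairs.append((1.0 / rec.r2_original - 1.0, rec.rr2))
    if len(pairs) < 3:
        raise ValueError("need at least 3 usable records")
    arr = np.asarray(pairs)
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return arr, float(r), float(p)


def meta_compare(rr2_a, rr2_b, weights, cohorts=None):
    """Compare paired per-cohort ratios of two clocks.

    Returns ``(wilcoxon_p, weighted_regression_p)``:

    - one-tailed paired Wilcoxon signed-rank p for the alternative that
      the ``a`` ratios exceed the ``b`` ratios;
    - two-tailed p of the clock-indicator coefficient in a weighted
      least-squares fit of ratio ~ clock + cohort with cohort sample
      sizes as weights.
    """
    a = np.asarray(rr2_a, dtype=float)
    b = np.asarray(rr2_b, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (a.shape == b.shape == w.shape):
        raise ValueError("ratios and weights must be paired by cohort")
    n = a.size
    if n < 5:
        raise ValueError("need >= 5 paired cohorts")
    if cohorts is None:
        cohorts = [f"cohort_{i}" for i in range(n)]

    diffs = a - b
    if np.all(diffs == 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(
            stats.wilcoxon(
                a, b, alternative="greater", zero_method="wilcox"
            ).pvalue
        )

    ratio = np.concatenate([a, b])
    clock = np.concatenate([np.ones(n), np.zeros(n)])
    cohort_fac = pd.Categorical(list(cohorts) * 2)
    X = pd.get_dummies(
        pd.DataFrame({"cohort": cohort_fac}), drop_first=True, dtype=float
    )
    X.insert(0, "clock", clock)
    X = sm.add_constant(X)
    fit = sm.WLS(ratio, X, weights=np.concatenate([w, w])).fit()
    reg_p = float(fit.pvalues["clock"])
    return wilcoxon_p, reg_p
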