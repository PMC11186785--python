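"""Cohort generation and elastic-net clock training/application.

A clock is a linear model on per-CpG standardized beta-values. Training
standardizes each CpG of the training set to mean 0 / SD 1, fits one
elastic-net model per penalty value on a fixed grid, and keeps the model
minimizing RMSE on an independent selection cohort. At application time
the default is to re-standardize each CpG within the evaluation dataset
("within-dataset" mode), which makes predictions invariant to per-CpG
location/scale shifts between datasets (e.g. cell-type baseline
differences); the training statistics can be applied instead
("train-frozen" mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from stochclock.simulate import SimParams, simulate_sample

__all__ = [
    "ArtificialCohort",
    "ClockModel",
    "default_lambda_grid",
    "generate_cohort",
    "train_clock",
    "predict_age",
]


def default_lambda_grid() -> np.ndarray:
    """Penalty grid 0 to 1 in steps of 0.001 (1,001 values)."""
    return np.round(np.arange(0, 1001) / 1000.0, 3)


@dataclass
class ArtificialCohort:
    """A simulated cohort: beta matrix (CpGs x samples) plus ages."""

    betas: pd.DataFrame
    ages: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.betas.shape[1] != len(self.ages):
            raise ValueError("ages length must equal sample count")


@dataclass
class ClockModel:
    """Linear age predictor on standardized beta-values."""

    cpg_ids: pd.Index
    weights: np.ndarray
    intercept: float
    alpha: float = 0.5
    lambda_: float = 0.0
    train_mean: np.ndarray | None = None
    train_sd: np.ndarray | None = None
    standardization: str = "within-dataset"
    selection_rmse: np.ndarray | None = field(default=None, repr=False)
    lambda_grid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cpg_ids = pd.Index(self.cpg_ids, name="cpg_id")
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.cpg_ids):
            raise ValueError("weights length must equal CpG count")
        if self.standardization not in ("within-dataset", "train-frozen"):
            raise ValueError(
                f"unknown standardization mode {self.standardization!r}"
            )

    @property
    def n_candidates(self) -> int:
        """Number of candidate models evaluated during selection."""
        if self.selection_rmse is None:
            return 1
        return len(self.selection_rmse)


def generate_cohort(
    young_pool: pd.DataFrame,
    effects: pd.DataFrame,
    params: SimParams,
    ages,
    samples_per_age: int,
    seed: int,
) -> ArtificialCohort:
    """Simulate a cohort with ``samples_per_age`` samples per age value.

    Each sample starts from a young-pool profile drawn uniformly at
    random (with replacement) and is advanced to its target age. Every
    sample owns an RNG spawned from the master seed and the sample
    index, so cohorts are reproducible and order-independent.
    """
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be nonempty")
    if young_pool.shape[1] == 0:
        raise ValueError("young pool is empty")
    if samples_per_age < 1:
        raise ValueError("samples_per_age must be >= 1")
    if np.any(ages < params.base_age):
        raise ValueError("all ages must be >= params.base_age")

    pool = young_pool.loc[effects.index]
    pool_values = pool.to_numpy(dtype=float)
    sample_ages = np.repeat(ages, samples_per_age)
    seeds = np.random.SeedSequence(seed).spawn(len(sample_ages))

    columns = {}
    draw_indices = np.empty(len(sample_ages), dtype=int)
    for i, (age, child) in enumerate(zip(sample_ages, seeds)):
        rng = np.random.default_rng(child)
        j = int(rng.integers(pool_values.shape[1]))
        draw_indices[i] = j
        columns[f"sim_{i:04d}"] = simulate_sample(
            pool_values[:, j], effects, params, age, rng
        )
    betas = pd.DataFrame(columns, index=effects.index.copy())
    return ArtificialCohort(
        betas=betas,
        ages=sample_ages,
        provenance={
            "seed": seed,
            "params": params,
            "draw_indices": draw_indices,
        },
    )


def _standardize_train(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    return (X - mean) / safe_sd, mean, sd, constant


def _apply_standardization(
    betas: pd.DataFrame, model: ClockModel, mode: str
) -> np.ndarray:
    X = betas.loc[model.cpg_ids].to_numpy(dtype=float).T
    if mode == "train-frozen":
        if model.train_mean is None or model.train_sd is None:
            raise ValueError("model carries no training statistics")
        sd = np.where(model.train_sd == 0, 1.0, model.train_sd)
        return (X - model.train_mean) / sd
    if X.shape[0] < 3:
        raise ValueError(
            "within-dataset standardization needs >= 3 samples"
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    # constant CpGs in the evaluation set are mapped to z = 0
    return (X - mean) / sd


def train_clock(
    train: ArtificialCohort,
    select: ArtificialCohort,
    alpha: float = 0.5,
    lambda_grid: np.ndarray | None = None,
    standardization: str = "within-dataset",
) -> ClockModel:
    """Fit one elastic-net model per penalty and keep the RMSE winner.

    ``alpha`` is the L1/L2 mixing weight; the penalty strength lambda is
    swept over ``lambda_grid`` (default 0..1 step 0.001). Lambda 0 is an
    unpenalized least-squares fit. Selection-set RMSE decides; ties go
    to the smallest lambda. Zero-variance training CpGs get weight 0.
    """
    if not train.betas.index.equals(select.betas.index):
        raise ValueError("train and select cohorts cover different CpGs")
    if len(np.unique(train.ages)) < 2:
        raise ValueError("training ages are degenerate (single value)")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    X = train.betas.to_numpy(dtype=float).T
    y = np.asarray(train.ages, dtype=float)
    Z, mean, sd, constant = _standardize_train(X)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} zero-variance CpGs excluded from fit",
            stacklevel=2,
        )
    Z_fit = Z[:, ~constant]

    # selection set standardized in the model's application mode
    n_cpgs = X.shape[1]
    probe = ClockModel(
        cpg_ids=train.betas.index,
        weights=np.zeros(n_cpgs),
        intercept=0.0,
        train_mean=mean,
        train_sd=sd,
        standardization=standardization,
    )
    Z_sel = _apply_standardization(select.betas, probe, standardization)
    y_sel = np.asarray(select.ages, dtype=float)

    best = None  # (rmse, lambda, weights_fit, intercept)
    rmses = np.empty(len(lambda_grid))
    enet = None
    # sweep penalties from strongest to weakest so warm starts help
    order = np.argsort(lambda_grid)[::-1]
    weights_by_pos = {}
    for pos in order:
        lam = lambda_grid[pos]
        if lam == 0.0:
            coef, *_ = np.linalg.lstsq(
                np.column_stack([Z_fit, np.ones(len(y))]), y, rcond=None
            )
            w_fit, intercept = coef[:-1], float(coef[-1])
        else:
            if enet is None:
                enet = ElasticNet(
                    alpha=lam,
                    l1_ratio=alpha,
                    max_iter=5000,
                    warm_start=True,
                    tol=1e-6,
                )
            else:
                enet.set_params(alpha=lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                enet.fit(Z_fit, y)
            w_fit, intercept = enet.coef_.copy(), float(enet.intercept_)
        weights_by_pos[pos] = (w_fit, intercept)

    for pos, lam in enumerate(lambda_grid):
        w_fit, intercept = weights_by_pos[pos]
        w = np.zeros(n_cpgs)
        w[~constant] = w_fit
        pred = Z_sel @ w + intercept
        rmse = float(np.sqrt(np.mean((pred - y_sel) ** 2)))
        rmses[pos] = rmse
        if best is None or rmse < best[0] - 1e-15:
            best = (rmse, lam, w, intercept)

    assert best is not None
    _, lam, w, intercept = best
    return ClockModel(
        cpg_ids=train.betas.index,
        weights=w,
        intercept=intercept,
        alpha=alpha,
        lambda_=float(lam),
        train_mean=mean,
        train_sd=sd,
        standardization=standardization,
        selection_rmse=rmses,
        lambda_grid=lambda_grid,
    )


def predict_age(
    model: ClockModel,
    betas: pd.DataFrame,
    standardization: str | None = None,
) -> np.ndarray:
    """Apply a clock to a beta matrix (CpGs x samples).

    ``standardization`` overrides the model's default mode. Raises on
    CpGs missing from ``betas``.
    """
    mode = standardization or model.standardization
    missing = model.cpg_ids.difference(betas.index)
    if len(missing):
        raise KeyError(
            f"evaluation matrix missing {len(missing)} clock CpGs: "
            f"{missing.tolist()[:5]}"
        )
    Z = _apply_standardization(betas, model, mode)
    return Z @ model.weights + model.intercept
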