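"""Readers/writers for the pipeline's delimited-text artifacts.

All matrices travel as TSV/CSV with a leading CpG-id column; files
written by this module carry ``#``-prefixed provenance header lines
(stage, seed, config hash) that the readers skip.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stochclock.clocks import ClockModel
from stochclock.fit import FitResult

__all__ = [
    "RunConfig",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clock_coefficients",
    "write_clock_coefficients",
    "write_fit_result",
    "read_fit_result",
    "provenance_header",
]


@dataclass
class RunConfig:
    """Defaults reproducing the documented protocol end to end."""

    seed: int = 0
    n_cpgs: int = 353
    n_young: int = 43
    n_old: int = 11
    steps_per_year: int = 35
    base_age: float = 45.0
    age_min: int = 45
    age_max: int = 83
    samples_per_age: int = 5
    alpha: float = 0.5
    lambda_step: float = 0.001
    lambda_max: float = 1.0
    standardization: str = "within-dataset"
    fit_resolution: int = 11
    fit_depth: int = 3
    fit_sims_per_pair: int = 50
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**known)
        cfg.extra = unknown
        return cfg

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "extra"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def lambda_grid(self) -> np.ndarray:
        n = int(round(self.lambda_max / self.lambda_step)) + 1
        return np.round(np.arange(n) * self.lambda_step, 6)

    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1, dtype=float)


def provenance_header(stage: str, seed, config: RunConfig | None = None) -> str:
    parts = [f"stage={stage}", f"seed={seed}"]
    if config is not None:
        parts.append(f"config_hash={config.digest()}")
    return "# " + " ".join(parts)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def write_beta_matrix(betas: pd.DataFrame, path, header: str | None = None):
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        betas.to_csv(fh, sep=_sep_for(path), index_label="cpg_id")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read and validate a CpG x sample beta matrix.

    Values must be finite and in [0, 1]; duplicate CpG ids and missing
    cells are rejected with coordinates in the message.
    """
    path = Path(path)
    betas = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    betas.index.name = "cpg_id"
    if betas.index.has_duplicates:
        dupes = betas.index[betas.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG ids: {dupes[:5]}")
    try:
        values = betas.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path.name}: {exc}") from exc
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing value at ({betas.index[r]}, {betas.columns[c]})"
        )
    bad = (values < 0) | (values > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"beta-value {values[r, c]} out of [0, 1] at "
            f"({betas.index[r]}, {betas.columns[c]})"
        )
    return betas


def write_sample_sheet(meta: pd.DataFrame, path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        meta.to_csv(fh, index_label="sample_id")


def read_sample_sheet(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col="sample_id", comment="#")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample_ids in sample sheet")
    if "age" not in meta.columns:
        raise ValueError("sample sheet must have an 'age' column")
    ages = meta["age"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ages)) or np.any(ages < 0):
        raise ValueError("ages must be finite and >= 0")
    frac_cols = [c for c in meta.columns if c.startswith("frac_")]
    if frac_cols:
        sums = meta[frac_cols].to_numpy(dtype=float).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("fraction rows must sum to 1 within 1e-6")
    return meta


def write_clock_coefficients(model: ClockModel, path):
    """Serialize a clock: JSON header line + coefficient CSV body."""
    header = {
        "intercept": model.intercept,
        "alpha": model.alpha,
        "lambda": model.lambda_,
        "standardization": model.standardization,
    }
    table = pd.DataFrame(
        {"cpg_id": model.cpg_ids, "weight": model.weights}
    )
    if model.train_mean is not None:
        table["train_mean"] = model.train_mean
        table["train_sd"] = model.train_sd
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        table.to_csv(fh, index=False)


def read_clock_coefficients(path) -> ClockModel:
    """Load a clock coefficient table.

    Accepts third-party tables in the same shape. Training statistics
    columns switch the model to train-frozen mode; unknown extra columns
    are ignored with a warning. A missing intercept header is an error
    (external clocks with nonlinear age transforms are out of scope and
    must be converted by the caller).
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(
                "clock file lacks the JSON header line with the intercept"
            )
        header = json.loads(first[1:])
        table = pd.read_csv(fh)
    if "intercept" not in header:
        raise ValueError("clock header missing 'intercept'")
    for col in ("cpg_id", "weight"):
        if col not in table.columns:
            raise ValueError(f"clock table missing column {col!r}")
    if table["cpg_id"].duplicated().any():
        raise ValueError("duplicate CpGs in clock table")
    known = {"cpg_id", "weight", "train_mean", "train_sd"}
    extra = set(table.columns) - known
    if extra:
        warnings.warn(f"ignoring extra clock columns: {sorted(extra)}",
                      stacklevel=2)
    has_stats = {"train_mean", "train_sd"} <= set(table.columns)
    mode = header.get(
        "standardization", "train-frozen" if has_stats else "within-dataset"
    )
    return ClockModel(
        cpg_ids=pd.Index(table["cpg_id"], name="cpg_id"),
        weights=table["weight"].to_numpy(dtype=float),
        intercept=float(header["intercept"]),
        alpha=float(header.get("alpha", 0.5)),
        lambda_=float(header.get("lambda", 0.0)),
        train_mean=table["train_mean"].to_numpy(float) if has_stats else None,
        train_sd=table["train_sd"].to_numpy(float) if has_stats else None,
        standardization=mode,
    )


def write_fit_result(result: FitResult, path):
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)


def read_fit_result(path) -> FitResult:
    with open(path) as fh:
        data = json.load(fh)
    return FitResult(
        gamma=data["gamma"],
        sigma=data["sigma"],
        mae=data["mae"],
        trace=pd.DataFrame.from_records(data["trace"]),
    )
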