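"""Dataset reading, run configuration and report writing."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import Dataset

__all__ = ["RunConfig", "read_dataset", "write_json", "write_tsv"]


@dataclass(frozen=True)
class RunConfig:
    """Options for a full analysis run; defaults follow common practice for
    this model family (alpha 0.05, cutoff 0.5, harmonics capped at 3)."""

    response_column: str = "y"
    predictor_columns: tuple[str, ...] = ()   # empty = every other column
    alpha: float = 0.05
    Kmax: int = 3
    cutoff: float = 0.5
    rescale_cosine: bool = False
    search_mode: str = "exhaustive"
    sensitivity_class: int = 0
    seed: int = 0
    output_dir: str = "fsnblr_out"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")
        if self.Kmax < 1:
            raise ValueError("Kmax must be at least 1")
        if self.search_mode not in ("exhaustive", "greedy"):
            raise ValueError(f"unknown search_mode: {self.search_mode!r}")
        if self.sensitivity_class not in (0, 1):
            raise ValueError("sensitivity_class must be 0 or 1")
        object.__setattr__(self, "predictor_columns",
                           tuple(self.predictor_columns))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_dataset(path, config: RunConfig | None = None) -> Dataset:
    """Read a header CSV into a validated Dataset.

    The response column must be coercible to {0, 1}; missing values anywhere
    are rejected with row-indexed diagnostics.
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    if config.response_column not in df.columns:
        raise ValueError(f"response column {config.response_column!r} not found")
    predictors = list(config.predictor_columns) or [
        c for c in df.columns if c != config.response_column
    ]
    missing = [c for c in predictors if c not in df.columns]
    if missing:
        raise ValueError(f"predictor columns not found: {missing}")

    sub = df[[config.response_column] + predictors]
    na_rows = sub.index[sub.isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(f"missing values in rows: {na_rows[:10]}")

    y = pd.to_numeric(df[config.response_column], errors="coerce").to_numpy()
    bad = np.where(~np.isin(y, (0.0, 1.0)))[0]
    if bad.size:
        raise ValueError(
            f"response must be 0/1; offending rows: {bad[:10].tolist()}"
        )
    X = df[predictors].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        rows = np.where(~np.all(np.isfinite(X), axis=1))[0]
        raise ValueError(f"non-numeric predictor values in rows: {rows[:10].tolist()}")
    return Dataset(y, X, tuple(predictors))


def write_json(obj, path) -> None:
    """Write a JSON report with stable key order and native types."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)
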