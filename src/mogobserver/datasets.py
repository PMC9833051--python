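"""Trial-table containers and delimited-text readers/writers.

Two psychophysical dataset kinds are supported:

* point estimation — one row per trial with the presented stimulus ``x`` and the
  reported estimate ``xhat``, plus a condition label mapping to a noise level;
* 2AFC — one row per trial with the stimulus pair ``x1``, ``x2``, the condition
  labels of the two intervals, and the binary response (1 = "stimulus 2 larger").

Files are plain text with a header row; comma and tab delimiters are
auto-detected.  Validation reports the offending row and column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "EstimationDataset",
    "TwoAFCDataset",
    "read_dataset",
]

_EST_COLUMNS = ["trial", "condition", "x", "xhat"]
_AFC_COLUMNS = ["trial", "condition1", "condition2", "x1", "x2", "response"]


@dataclass(frozen=True)
class EstimationDataset:
    """Point-estimation trials: stimulus ``x``, report ``xhat``, condition label."""

    x: np.ndarray
    xhat: np.ndarray
    condition: np.ndarray  # string labels, one per trial
    trial: np.ndarray

    def __post_init__(self):
        n = self.x.size
        if n == 0:
            raise ValueError("no trials")
        if not (self.xhat.size == self.condition.size == self.trial.size == n):
            raise ValueError("column lengths differ")
        for name in ("x", "xhat"):
            col = getattr(self, name)
            bad = np.nonzero(~np.isfinite(col))[0]
            if bad.size:
                raise ValueError(f"non-finite value in column {name!r} at row {bad[0]}")

    @property
    def n_trials(self) -> int:
        return self.x.size

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.condition.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": self.trial, "condition": self.condition, "x": self.x, "xhat": self.xhat}
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EstimationDataset":
        _require_columns(df, _EST_COLUMNS)
        return cls(
            x=_numeric_column(df, "x"),
            xhat=_numeric_column(df, "xhat"),
            condition=df["condition"].astype(str).to_numpy(),
            trial=df["trial"].to_numpy(),
        )


@dataclass(frozen=True)
class TwoAFCDataset:
    """2AFC trials: stimulus pair, per-interval condition labels, binary response."""

    x1: np.ndarray
    x2: np.ndarray
    condition1: np.ndarray
    condition2: np.ndarray
    response: np.ndarray
    trial: np.ndarray

    def __post_init__(self):
        n = self.x1.size
        if n == 0:
            raise ValueError("no trials")
        sizes = {
            "x2": self.x2.size, "condition1": self.condition1.size,
            "condition2": self.condition2.size, "response": self.response.size,
            "trial": self.trial.size,
        }
        if any(v != n for v in sizes.values()):
            raise ValueError("column lengths differ")
        for name in ("x1", "x2"):
            col = getattr(self, name)
            bad = np.nonzero(~np.isfinite(col))[0]
            if bad.size:
                raise ValueError(f"non-finite value in column {name!r} at row {bad[0]}")
        bad = np.nonzero(~np.isin(self.response, (0, 1)))[0]
        if bad.size:
            raise ValueError(
                f"non-binary response {self.response[bad[0]]!r} in column 'response' "
                f"at row {bad[0]}"
            )

    @property
    def n_trials(self) -> int:
        return self.x1.size

    @property
    def conditions(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.condition1.tolist())
        seen.update(dict.fromkeys(self.condition2.tolist()))
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "condition1": self.condition1,
                "condition2": self.condition2,
                "x1": self.x1,
                "x2": self.x2,
                "response": self.response,
            }
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TwoAFCDataset":
        _require_columns(df, _AFC_COLUMNS)
        resp = _numeric_column(df, "response")
        return cls(
            x1=_numeric_column(df, "x1"),
            x2=_numeric_column(df, "x2"),
            condition1=df["condition1"].astype(str).to_numpy(),
            condition2=df["condition2"].astype(str).to_numpy(),
            response=resp.astype(int) if np.all(np.isin(resp, (0, 1))) else resp,
            trial=df["trial"].to_numpy(),
        )


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")


def _numeric_column(df: pd.DataFrame, name: str) -> np.ndarray:
    col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(col))[0]
    if bad.size:
        raise ValueError(f"non-numeric or non-finite value in column {name!r} at row {bad[0]}")
    return col


def read_dataset(path, kind: Literal["estimation", "2afc"]):
    """Read a trial table from delimited text (comma or tab, header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: no trials (empty file)")
    header = text.splitlines()[0]
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: no trials")
    if kind == "estimation":
        return EstimationDataset.from_frame(df)
    if kind == "2afc":
        return TwoAFCDataset.from_frame(df)
    raise ValueError(f"unknown dataset kind {kind!r}")
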