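"""Delimited-text I/O and run configuration.

Feature matrices are read from CSV/TSV with subjects as rows, a header row of
variable names and one designated 0/1 label column.  Selection tables are
written as CSV mirroring the fitted table's column order and round-trip
losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Weights
from .model import TABLE_COLUMNS
from .nulldist import DEFAULT_M, DEFAULT_SEED

__all__ = [
    "RunConfig",
    "read_feature_matrix",
    "write_selection_table",
    "read_selection_table",
]


@dataclass
class RunConfig:
    """Configuration of a selection run; YAML-loadable, CLI flags override."""

    input: str = ""
    label_column: str = "group"
    w0: float = 0.5
    w1: float = 0.5
    alpha: float = 0.05
    mode: str = "min"
    m: int = DEFAULT_M
    seed: int = DEFAULT_SEED
    output_dir: str = "."
    transpose: bool = False

    def __post_init__(self) -> None:
        Weights(self.w0, self.w1)  # validate
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.mode not in ("up", "down", "min"):
            raise ValueError(f"mode must be 'up', 'down' or 'min', got {self.mode!r}")

    @property
    def weights(self) -> Weights:
        return Weights(self.w0, self.w1)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        loaded.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**loaded)

    def to_dict(self) -> dict:
        return asdict(self)


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_feature_matrix(
    path: str | Path, label_column: str, transpose: bool = False
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a delimited feature matrix with a binary label column.

    Returns ``(matrix, labels, names)`` with subjects as rows.  With
    ``transpose=True`` the file is read variables-as-rows (first column =
    variable names, one row named ``label_column`` holding the labels).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_delimiter(path))
    if transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
        frame.columns.name = None
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    raw_labels = frame[label_column]
    bad = raw_labels[~raw_labels.isin([0, 1])]
    if not bad.empty:
        raise ValueError(
            f"label column {label_column!r} must contain only 0/1; "
            f"offending row {bad.index[0]} has value {bad.iloc[0]!r}"
        )
    features = frame.drop(columns=[label_column])
    numeric = features.apply(pd.to_numeric, errors="coerce")
    mask = numeric.isna() & ~features.isna()
    if mask.to_numpy().any():
        r, c = np.argwhere(mask.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {mask.index[r]}, column {mask.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at row {numeric.index[r]}, column {numeric.columns[c]!r}"
        )
    return (
        numeric.to_numpy(dtype=float),
        raw_labels.to_numpy(dtype=int),
        [str(c) for c in numeric.columns],
    )


def write_selection_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a selection table as CSV in the documented column order.

    p-values and error rates keep full precision (well beyond six significant
    digits) so the file round-trips losslessly.
    """
    path = Path(path)
    table[TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_selection_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path))
    missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"selection table {Path(path).name} lacks columns {missing}")
    frame["significant"] = frame["significant"].astype(bool)
    return frame[TABLE_COLUMNS]
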