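"""Reading and writing of response matrices, covariate tables, and result JSON.

The on-disk interchange formats are deliberately plain: delimited text (CSV
with a header row) for person-level data and JSON for structured results, so
that every artifact can be inspected, diffed, and versioned.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemResponseMatrix",
    "read_response_matrix",
    "read_covariates",
    "write_covariates",
    "dump_json",
]


@dataclass(frozen=True)
class ItemResponseMatrix:
    """Persons x items binary (0/1) response data.

    Parameters
    ----------
    values : ndarray of shape (n_persons, n_items)
        0/1 integer responses; 1 codes a correct (keyed) response.
    item_ids : tuple of str
        Column labels, one per item, unique.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("response matrix must be two-dimensional")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"non-binary cell at row {bad[0] + 1}, column "
                f"{self.item_ids[bad[1]] if len(self.item_ids) > bad[1] else bad[1]!r}"
            )
        if len(self.item_ids) != values.shape[1]:
            raise ValueError("item_ids length must match the number of columns")
        if len(set(self.item_ids)) != len(self.item_ids):
            dupes = sorted({i for i in self.item_ids if self.item_ids.count(i) > 1})
            raise ValueError(f"duplicate item names: {dupes}")
        object.__setattr__(self, "values", values.astype(np.int8, copy=False))
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "ItemResponseMatrix":
        idx = list(indices)
        return ItemResponseMatrix(
            self.values[:, idx], tuple(self.item_ids[i] for i in idx)
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ItemResponseMatrix":
        return cls(frame.to_numpy(), tuple(map(str, frame.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_ids))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_response_matrix(path: str | Path) -> ItemResponseMatrix:
    """Read a persons x items 0/1 CSV (header row = item names)."""
    with open(path) as handle:
        header = next(csv.reader(handle))
    if len(set(header)) != len(header):
        dupes = sorted({name for name in header if header.count(name) > 1})
        raise ValueError(f"duplicate item names in {path}: {dupes}")
    frame = pd.read_csv(path)
    values = frame.to_numpy()
    mask = ~np.isin(values, (0, 1))
    if mask.any():
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"non-binary cell {values[r, c]!r} at row {r + 1}, "
            f"column {frame.columns[c]!r} in {path}"
        )
    return ItemResponseMatrix.from_dataframe(frame)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a persons x covariates numeric CSV (header row = covariate names)."""
    frame = pd.read_csv(path)
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric covariate columns in {path}: {non_numeric}")
    return frame


def write_covariates(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


class _ResultEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102 - json hook
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def dump_json(obj, path: str | Path) -> None:
    """Serialize results (dataclasses, arrays) to pretty-printed JSON."""
    Path(path).write_text(json.dumps(obj, cls=_ResultEncoder, indent=2) + "\n")
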