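"""Descriptor tables: the tabular container every pipeline stage consumes.

A :class:`DescriptorTable` is an n-compound by p-descriptor matrix with
unique compound ids, unique descriptor names, no missing values, and an
optional target column ``logIGC50inv`` = log10(1/IGC50) in (mmol/L)^-1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET_COLUMN = "logIGC50inv"
ID_COLUMN = "compound_id"


class TableError(ValueError):
    """Schema or value problem in a descriptor table."""


@dataclass
class DescriptorTable:
    """Named descriptor matrix plus optional toxicity target.

    Attributes
    ----------
    ids : list of str
        Compound identifiers, unique.
    X : pandas.DataFrame
        n x p matrix of finite descriptor values; columns are descriptor
        names.
    y : pandas.Series or None
        Target log10(1/IGC50); absent for prediction-only tables.
    """

    ids: list[str]
    X: pd.DataFrame
    y: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n < 1:
            raise TableError("table must contain at least one compound")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise TableError(f"duplicate compound_id: {dupes}")
        if self.X.shape[0] != n:
            raise TableError("ids and value matrix disagree on n")
        if self.X.shape[1] < 1:
            raise TableError("table must contain at least one descriptor")
        cols = list(self.X.columns)
        if len(set(cols)) != len(cols):
            raise TableError("duplicate descriptor names")
        vals = self.X.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
            bad = self._first_bad_cell()
            raise TableError(f"non-finite or non-numeric value at {bad}")
        if self.y is not None:
            yv = self.y.to_numpy()
            if len(yv) != n:
                raise TableError("target length does not match n")
            if not np.all(np.isfinite(yv.astype(float))):
                raise TableError("non-finite target value")

    def _first_bad_cell(self) -> str:
        for col in self.X.columns:
            colv = pd.to_numeric(self.X[col], errors="coerce")
            bad = colv.index[~np.isfinite(colv.to_numpy(dtype=float))]
            if len(bad):
                row = bad[0]
                return f"row {self.ids[self.X.index.get_loc(row)]!r}, column {col!r}"
        return "unknown cell"

    # -- basic views -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def descriptor_names(self) -> list[str]:
        return [str(c) for c in self.X.columns]

    def values(self, features: list[str] | None = None) -> np.ndarray:
        cols = features if features is not None else self.descriptor_names
        missing = [c for c in cols if c not in self.X.columns]
        if missing:
            raise TableError(f"unknown descriptor column(s): {missing}")
        return self.X[cols].to_numpy(dtype=float)

    def target(self) -> np.ndarray:
        if self.y is None:
            raise TableError(f"table has no target column {TARGET_COLUMN!r}")
        return self.y.to_numpy(dtype=float)

    def subset_rows(self, index: np.ndarray) -> "DescriptorTable":
        index = np.asarray(index)
        return DescriptorTable(
            ids=[self.ids[i] for i in index],
            X=self.X.iloc[index].reset_index(drop=True),
            y=None if self.y is None else self.y.iloc[index].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def select_features(self, features: list[str]) -> "DescriptorTable":
        missing = [c for c in features if c not in self.X.columns]
        if missing:
            raise TableError(f"unknown descriptor column(s): {missing}")
        return DescriptorTable(
            ids=list(self.ids),
            X=self.X[list(features)].copy(),
            y=None if self.y is None else self.y.copy(),
            meta=dict(self.meta),
        )

    # -- IO ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, ID_COLUMN, self.ids)
        if self.y is not None:
            out[TARGET_COLUMN] = self.y.to_numpy()
        return out

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def read_table(path_or_buf, require_target: bool = True) -> DescriptorTable:
    """Read a descriptor CSV: ``compound_id,<descriptors...>[,logIGC50inv]``.

    Every descriptor cell must parse as a finite number; offending cells are
    reported with row id and column name.  Duplicate ids are rejected.
    """
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    if ID_COLUMN not in df.columns:
        raise TableError(f"missing required column {ID_COLUMN!r}")
    ids = [str(v) for v in df[ID_COLUMN]]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise TableError(f"duplicate compound_id: {dupes}")

    value_cols = [c for c in df.columns if c not in (ID_COLUMN, TARGET_COLUMN)]
    if not value_cols:
        raise TableError("no descriptor columns found")
    X = pd.DataFrame(index=range(len(df)))
    for col in value_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(parsed.to_numpy(dtype=float)))
        if len(bad):
            r = bad[0]
            raise TableError(
                f"cell {df[col].iloc[r]!r} at row {ids[r]!r}, column {col!r} "
                "is not a finite number"
            )
        X[col] = parsed.to_numpy(dtype=float)

    y = None
    if TARGET_COLUMN in df.columns:
        parsed = pd.to_numeric(df[TARGET_COLUMN], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(parsed.to_numpy(dtype=float)))
        if len(bad):
            r = bad[0]
            raise TableError(
                f"cell {df[TARGET_COLUMN].iloc[r]!r} at row {ids[r]!r}, "
                f"column {TARGET_COLUMN!r} is not a finite number"
            )
        y = pd.Series(parsed.to_numpy(dtype=float), name=TARGET_COLUMN)
    elif require_target:
        raise TableError(f"missing target column {TARGET_COLUMN!r}")

    return DescriptorTable(ids=ids, X=X, y=y)
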