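"""Descriptor tables: the tabular container consumed by every pipeline stage.

A :class:`DescriptorTable` is a named numeric feature matrix with one binary
label per instance (1 = positive class, e.g. a substrate that yields reactive
metabolites).  Descriptor values are used raw — no scaling, weighting or
normalisation is applied anywhere in the pipeline — so the table preserves
the original magnitudes of its columns.

Tables are read from CSV/TSV files with a header row, or from ARFF files
where the label may be a two-valued nominal attribute.  Missing values are
rejected with the offending coordinate, never imputed: a silent fill would
corrupt the rankings every downstream statistic is built on.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = ["DescriptorTable", "read_table", "write_table"]

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}


@dataclass
class DescriptorTable:
    """Numeric descriptor matrix plus a binary label vector.

    Parameters
    ----------
    instance_ids : sequence of str
        Unique opaque identifiers, one per row.
    descriptor_names : sequence of str
        Unique column names, order preserved from the source file.
    values : ndarray of shape (n_total, n_descriptors)
        Real-valued descriptors; must be finite (no NaN/inf).
    labels : ndarray of shape (n_total,) or None
        Binary class vector (1 = positive).  ``None`` for unlabeled tables
        that are only ever scored, never fitted.
    """

    instance_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.instance_ids = [str(i) for i in self.instance_ids]
        self.descriptor_names = [str(c) for c in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.instance_ids) != n:
            raise ValueError(
                f"{len(self.instance_ids)} instance ids for {n} rows of values"
            )
        if len(self.descriptor_names) != d:
            raise ValueError(
                f"{len(self.descriptor_names)} descriptor names for {d} columns"
            )
        if len(set(self.instance_ids)) != n:
            dup = _first_duplicate(self.instance_ids)
            raise ValueError(f"duplicate instance id: {dup!r}")
        if len(set(self.descriptor_names)) != d:
            dup = _first_duplicate(self.descriptor_names)
            raise ValueError(f"duplicate descriptor name: {dup!r}")
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {self.instance_ids[r]!r}, "
                f"column {self.descriptor_names[c]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must be a vector matching the row count")
            uniq = set(np.unique(self.labels).tolist())
            if not uniq <= {0, 1}:
                raise ValueError(f"labels must be binary 0/1, found {sorted(uniq)}")
            self.labels = self.labels.astype(np.int8)

    # ------------------------------------------------------------------ stats
    @property
    def n_total(self) -> int:
        """Total number of instances (symbol *t* in the scoring model)."""
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def n_positive(self) -> int:
        """Count of positive labels (symbol *n* in the scoring model)."""
        if self.labels is None:
            raise ValueError("table has no labels")
        return int(self.labels.sum())

    @property
    def positive_rate(self) -> float:
        return self.n_positive / self.n_total

    @property
    def positive_percentage(self) -> float:
        """Positive rate expressed in percent (e.g. 14.1 for 138/977)."""
        return 100.0 * self.positive_rate

    def check_fit_ready(self) -> None:
        """Raise unless the table can train a model (both classes present)."""
        if self.labels is None:
            raise ValueError("cannot fit on an unlabeled table")
        if not 0 < self.n_positive < self.n_total:
            raise ValueError(
                "fitting requires both classes present: "
                f"{self.n_positive} positives of {self.n_total}"
            )

    # ----------------------------------------------------------------- access
    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"unknown descriptor {name!r}") from None
        return self.values[:, j]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        """Matrix restricted to `names`, in that order."""
        idx = []
        for name in names:
            try:
                idx.append(self.descriptor_names.index(name))
            except ValueError:
                raise KeyError(f"unknown descriptor {name!r}") from None
        return self.values[:, idx]

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        """A reduced table keeping only the given descriptor columns."""
        return DescriptorTable(
            instance_ids=list(self.instance_ids),
            descriptor_names=list(names),
            values=self.columns(names).copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def subset(self, mask_or_ids) -> "DescriptorTable":
        """Row subset by boolean mask or by a list of instance ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {v: i for i, v in enumerate(self.instance_ids)}
            idx = np.array([pos[str(i)] for i in mask_or_ids], dtype=int)
        return DescriptorTable(
            instance_ids=[self.instance_ids[i] for i in idx],
            descriptor_names=list(self.descriptor_names),
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    # ------------------------------------------------------------- conversion
    def to_dataframe(
        self, label_column: str = "label", id_column: str = "id"
    ) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, id_column, self.instance_ids)
        if self.labels is not None:
            df[label_column] = self.labels.astype(int)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str | None = "label",
        id_column: str | None = None,
        positive_class=None,
    ) -> "DescriptorTable":
        """Build a table from a DataFrame.

        The id column defaults to a column literally named ``id`` when present,
        otherwise the row index is used.  ``positive_class`` maps a two-valued
        categorical label onto 1; numeric/boolean labels need no mapping.
        """
        df = df.copy()
        if id_column is None and "id" in df.columns:
            id_column = "id"
        if id_column is not None:
            if id_column not in df.columns:
                raise ValueError(f"id column {id_column!r} not found")
            ids = df.pop(id_column).astype(str).tolist()
        else:
            ids = [str(i) for i in df.index]

        labels = None
        if label_column is not None:
            if label_column not in df.columns:
                raise ValueError(f"label column {label_column!r} not found")
            labels = _coerce_labels(df.pop(label_column), positive_class)

        for col in df.columns:
            if df[col].isna().any():
                r = int(np.flatnonzero(df[col].isna().to_numpy())[0])
                raise ValueError(
                    f"missing value at row {ids[r]!r}, column {col!r}"
                )
            if not pd.api.types.is_numeric_dtype(df[col]):
                try:
                    df[col] = pd.to_numeric(df[col])
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric descriptor column {col!r}"
                    ) from None
        return cls(
            instance_ids=ids,
            descriptor_names=list(map(str, df.columns)),
            values=df.to_numpy(dtype=float),
            labels=labels,
        )


def _first_duplicate(items) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _coerce_labels(series: pd.Series, positive_class) -> np.ndarray:
    """Coerce a label column to {0, 1}.

    Accepts numeric {0,1}, booleans, true/false strings, or an arbitrary
    two-valued categorical when ``positive_class`` names the positive level.
    """
    vals = series.to_numpy()
    if series.isna().any():
        r = int(np.flatnonzero(series.isna().to_numpy())[0])
        raise ValueError(f"missing label at row index {r}")
    # decode ARFF byte strings
    if vals.dtype.kind == "S" or any(isinstance(v, bytes) for v in vals[:1]):
        vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])

    if positive_class is not None:
        pos = str(positive_class)
        levels = sorted({str(v) for v in vals})
        if pos not in levels:
            raise ValueError(
                f"positive class {pos!r} not among label values {levels}"
            )
        if len(levels) != 2:
            raise ValueError(f"label is not two-valued: {levels}")
        return np.array([1 if str(v) == pos else 0 for v in vals], dtype=np.int8)

    if vals.dtype.kind == "b":
        return vals.astype(np.int8)
    if all(isinstance(v, numbers.Number) for v in vals):
        arr = np.asarray(vals, dtype=float)
        if not np.isin(arr, (0.0, 1.0)).all():
            bad = sorted(set(arr.tolist()) - {0.0, 1.0})
            raise ValueError(f"non-binary label values {bad}; expected 0/1")
        return arr.astype(np.int8)
    lowered = [str(v).strip().lower() for v in vals]
    if all(v in _TRUE_STRINGS | _FALSE_STRINGS for v in lowered):
        return np.array([1 if v in _TRUE_STRINGS else 0 for v in lowered], np.int8)
    levels = sorted(set(map(str, vals)))
    raise ValueError(
        f"cannot interpret label values {levels} as binary; "
        "pass positive_class to map a two-valued categorical"
    )


def read_table(
    path,
    label_column: str | None = "label",
    dialect: str | None = None,
    positive_class=None,
    id_column: str | None = None,
) -> DescriptorTable:
    """Read a descriptor table from CSV, TSV or ARFF.

    ``dialect`` is inferred from the file suffix when omitted.  All non-label
    columns must be numeric and complete; a missing cell raises with its
    row/column coordinates.  For ARFF a nominal label requires
    ``positive_class`` to name the positive level.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".arff": "arff"}.get(
            path.suffix.lower(), "csv"
        )
    if dialect not in ("csv", "tsv", "arff"):
        raise ValueError(f"unknown dialect {dialect!r}")

    if dialect == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
    else:
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep)
    return DescriptorTable.from_dataframe(
        df,
        label_column=label_column,
        id_column=id_column,
        positive_class=positive_class,
    )


def write_table(table: DescriptorTable, path, label_column: str = "label") -> None:
    """Write a table as CSV (always with an ``id`` column and header)."""
    table.to_dataframe(label_column=label_column).to_csv(path, index=False)
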