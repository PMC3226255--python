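"""Core data containers and delimited-text I/O.

The central container is :class:`MixedModeTable`: a samples x attributes
grid in which every attribute is tagged either ``continuous`` (finite
reals, e.g. expression levels) or ``categorical`` (symbols from a finite
alphabet).  An optional per-sample class label can ride along but is kept
strictly outside the attribute set: every unsupervised stage operates on
the attributes alone, and the labels re-enter only for post-hoc rule
scoring.

Missing values are rejected outright: every downstream statistic is a
plug-in estimate from a complete contingency table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

__all__ = [
    "CONTINUOUS",
    "CATEGORICAL",
    "MixedModeTable",
    "DiscreteCodes",
    "IntervalScheme",
    "read_table",
    "write_events",
    "read_events",
]


@dataclass
class DiscreteCodes:
    """Integer codes for one attribute: each code lies in ``[0, m)``."""

    codes: np.ndarray
    m: int

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.intp)
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.m):
            raise ValueError("codes out of range [0, m)")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class IntervalScheme:
    """Ordered cut-points mapping a continuous attribute to labelled intervals.

    Intervals are half-open ``[c_j, c_{j+1})`` with the final interval
    closed at the observed maximum, so the mapping is total over the
    attribute's observed range.  A mode discretized into three states uses
    the labels ``L``/``N``/``H`` (lowly / normally / highly expressed).
    """

    attribute: str
    cuts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cuts = np.asarray(self.cuts, dtype=float)
        self.labels = tuple(self.labels)
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need len(labels) == len(cuts) + 1")
        if self.cuts.size and not np.all(np.diff(self.cuts) > 0):
            raise ValueError("cuts must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.labels)

    def assign_codes(self, values: np.ndarray) -> np.ndarray:
        """Interval index per value under the [a, b) convention."""
        return np.searchsorted(self.cuts, np.asarray(values, dtype=float), side="right")

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Interval label per value."""
        lab = np.asarray(self.labels, dtype=object)
        return lab[self.assign_codes(values)]

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "cuts": [float(c) for c in self.cuts],
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalScheme":
        return cls(d["attribute"], np.asarray(d["cuts"], dtype=float), tuple(d["labels"]))


@dataclass
class MixedModeTable:
    """Samples x attributes table of mixed continuous/categorical data.

    Parameters
    ----------
    values
        DataFrame with one column per attribute.  Continuous columns hold
        finite floats, categorical columns hold symbols (strings).
    kinds
        Mapping attribute name -> ``"continuous"`` or ``"categorical"``.
    class_labels
        Optional per-sample symbols, *never* consulted by unsupervised
        stages.
    """

    values: pd.DataFrame
    kinds: dict[str, str]
    class_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("table must have at least one sample and one attribute")
        missing = set(self.values.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"kinds missing for attributes: {sorted(missing)}")
        for name, kind in self.kinds.items():
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"unknown kind {kind!r} for {name!r}")
        for name in self.values.columns:
            col = self.values[name]
            if col.isna().any():
                raise ValueError(f"attribute {name!r} contains missing values")
            if self.kinds[name] == CONTINUOUS:
                arr = col.to_numpy(dtype=float)
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"continuous attribute {name!r} has non-finite values")
                self.values[name] = arr
            else:
                self.values[name] = col.astype(str)
        if self.class_labels is not None:
            if len(self.class_labels) != len(self.values):
                raise ValueError("class_labels length must equal sample count")
            if self.class_labels.isna().any():
                raise ValueError("class_labels contain missing values")
            self.class_labels = self.class_labels.astype(str).reset_index(drop=True)
        self.values = self.values.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def attribute_names(self) -> list[str]:
        return list(self.values.columns)

    def kind(self, name: str) -> str:
        return self.kinds[name]

    def is_continuous(self, name: str) -> bool:
        return self.kinds[name] == CONTINUOUS

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def without_class(self) -> "MixedModeTable":
        """A copy with the class labels dropped (for label-blindness tests)."""
        return MixedModeTable(self.values.copy(), dict(self.kinds), None)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        kind_hints: dict[str, str] | None = None,
        class_column: str | None = None,
    ) -> "MixedModeTable":
        """Build a table from a DataFrame, auto-typing columns.

        A column on which every entry parses as a number is continuous;
        anything else is categorical.  ``kind_hints`` overrides the
        auto-typing per column.
        """
        if df.shape[0] == 0:
            raise ValueError("empty table")
        df = df.copy()
        labels = None
        if class_column is not None:
            if class_column not in df.columns:
                raise KeyError(f"class column {class_column!r} not in table")
            labels = df.pop(class_column)
        if df.shape[1] == 0:
            raise ValueError("table has no attributes beyond the class column")
        kinds: dict[str, str] = {}
        hints = kind_hints or {}
        for name in df.columns:
            if name in hints:
                kinds[name] = hints[name]
                continue
            parsed = pd.to_numeric(df[name], errors="coerce")
            kinds[name] = CONTINUOUS if not parsed.isna().any() else CATEGORICAL
            if kinds[name] == CONTINUOUS:
                df[name] = parsed
        return cls(df, kinds, labels)


def _detect_delimiter(path: str) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    # auto-detection is deliberately limited to comma vs tab
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_table(
    path: str,
    kind_hints: dict[str, str] | None = None,
    class_column: str | None = None,
    delimiter: str | None = None,
) -> MixedModeTable:
    """Read a delimited text file (header row mandatory) into a table.

    Columns are auto-typed (all-numeric -> continuous, else categorical)
    unless overridden by ``kind_hints``; ``class_column``, when named, is
    removed from the attribute set and stored separately.
    """
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str, skipinitialspace=True)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    return MixedModeTable.from_dataframe(df, kind_hints=kind_hints, class_column=class_column)


def write_events(table: pd.DataFrame, path: str) -> None:
    """Write an event table (interval/value labels) as TSV.

    Round-trips losslessly through :func:`read_events` because every cell
    is already a symbol.
    """
    table.to_csv(path, sep="\t", index=False)


def read_events(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return df
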