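"""Interdependence redundancy between mixed-mode attributes.

The pairwise similarity underlying the whole pipeline is the normalized
interdependence redundancy

    R(G_i : G_j) = I(G_i : G_j) / H(G_i : G_j),

mutual information divided by joint entropy, a symmetric measure in
[0, 1] that is insensitive to the number of attribute states.  Both I and
H are plug-in estimates from the two attributes' contingency table:
categorical attributes contribute their native symbols, continuous ones
are first partitioned into ``m`` equal-frequency bins.

The bin count grows slowly with the sample size.  In mixed-mode data R
must stay comparable across categorical-categorical, categorical-
continuous and continuous-continuous pairs, and the joint entropy in the
denominator grows like log2(m) for a binned attribute; letting m grow as
a power of |T| therefore systematically shrinks R for every pair touching
a continuous attribute and distorts the clustering objective.  We use

    m = max(2, floor(ln(|T| / alpha)))

where ``alpha`` is the rule-of-thumb minimum number of data points per
contingency-table cell (2 or 3 in practice): 6 bins at |T| = 1800,
3 bins at the ~60-sample scale typical of expression studies.

The cluster-level quantities MR (sum of R between one attribute and all
other members of its cluster) and SR (sum of the cluster modes' MR) are
defined here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np

from .data import CONTINUOUS, DiscreteCodes, MixedModeTable

__all__ = [
    "choose_bin_count",
    "bin_continuous",
    "categorical_codes",
    "mutual_information",
    "joint_entropy",
    "redundancy",
    "RedundancyMatrix",
    "redundancy_matrix",
    "multiple_redundancy",
]


def choose_bin_count(sample_size: int, alpha: int = 3) -> int:
    """Number of equal-frequency bins for a continuous attribute.

    ``m = max(2, floor(ln(sample_size / alpha)))`` -- logarithmic growth
    keeps binned cardinalities commensurate with typical categorical
    alphabets while still refining with more data.
    """
    if alpha < 1:
        raise ValueError("alpha must be a positive integer")
    if alpha > sample_size:
        raise ValueError("alpha cannot exceed the sample size")
    return max(2, math.floor(math.log(sample_size / alpha)))


def bin_continuous(values: np.ndarray, m: int) -> DiscreteCodes:
    """Equal-frequency (quantile) binning into at most ``m`` bins.

    Ties sit entirely in the lower bin (cut-points are compared with
    strict inequality from below), so duplicated quantiles collapse bins:
    a constant vector yields a single occupied bin.
    """
    values = np.asarray(values, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > len(values):
        raise ValueError("more bins than values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    edges = np.quantile(values, np.linspace(0, 1, m + 1)[1:-1])
    codes = np.searchsorted(edges, values, side="left")
    # collapse empty bins so codes are dense in [0, m_eff)
    uniq, codes = np.unique(codes, return_inverse=True)
    return DiscreteCodes(codes, len(uniq))


def categorical_codes(values: Iterable) -> DiscreteCodes:
    """Dense integer codes for a categorical column."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    uniq, codes = np.unique(arr.astype(str), return_inverse=True)
    return DiscreteCodes(codes, len(uniq))


def _joint_probs(x: DiscreteCodes, y: DiscreteCodes) -> np.ndarray:
    if len(x) != len(y):
        raise ValueError("code vectors must have equal length")
    counts = np.bincount(x.codes * y.m + y.codes, minlength=x.m * y.m)
    return counts.reshape(x.m, y.m) / len(x)


def mutual_information(x: DiscreteCodes, y: DiscreteCodes) -> float:
    """Plug-in mutual information I(x; y) in bits; zero cells contribute 0."""
    p = _joint_probs(x, y)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def joint_entropy(x: DiscreteCodes, y: DiscreteCodes) -> float:
    """Plug-in joint entropy H(x, y) in bits."""
    p = _joint_probs(x, y)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def _codes_for(table: MixedModeTable, name: str, alpha: int) -> DiscreteCodes:
    col = table.column(name)
    if table.is_continuous(name):
        m = choose_bin_count(table.n_samples, alpha)
        return bin_continuous(col, m)
    return categorical_codes(col)


def redundancy(table: MixedModeTable, i: int, j: int, alpha: int = 3) -> float:
    """R between attributes ``i`` and ``j`` of a mixed-mode table.

    Returns 0 when both attributes are constant (H = 0: no information to
    share), 1 on the diagonal for any attribute with >= 2 distinct values.
    """
    names = table.attribute_names
    x = _codes_for(table, names[i], alpha)
    y = _codes_for(table, names[j], alpha)
    h = joint_entropy(x, y)
    if h == 0.0:
        return 0.0
    return mutual_information(x, y) / h


@dataclass
class RedundancyMatrix:
    """Symmetric attributes x attributes matrix of R values in [0, 1]."""

    values: np.ndarray
    attribute_names: list[str]
    alpha: int
    bin_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.attribute_names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match attribute count")

    @property
    def n_attributes(self) -> int:
        return len(self.attribute_names)

    def index(self, name: str) -> int:
        return self.attribute_names.index(name)

    def to_dict(self) -> dict:
        return {
            "attribute_names": self.attribute_names,
            "alpha": self.alpha,
            "bin_count": self.bin_count,
            "values": self.values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RedundancyMatrix":
        return cls(np.asarray(d["values"]), list(d["attribute_names"]), d["alpha"], d["bin_count"])


def redundancy_matrix(table: MixedModeTable, alpha: int = 3) -> RedundancyMatrix:
    """The full pairwise R matrix, binning each continuous attribute once.

    Constant attributes get R = 0 against everything, including
    themselves: they carry no information and can never become modes.
    """
    names = table.attribute_names
    codes = [_codes_for(table, nm, alpha) for nm in names]
    n = len(names)
    R = np.zeros((n, n))
    for i in range(n):
        if codes[i].m >= 2:
            R[i, i] = 1.0
        for j in range(i + 1, n):
            h = joint_entropy(codes[i], codes[j])
            if h > 0.0:
                R[i, j] = R[j, i] = mutual_information(codes[i], codes[j]) / h
    m = choose_bin_count(table.n_samples, alpha) if any(
        table.is_continuous(nm) for nm in names
    ) else 0
    return RedundancyMatrix(R, names, alpha, m)


def multiple_redundancy(R: RedundancyMatrix | np.ndarray, i: int, cluster: Iterable[int]) -> float:
    """MR(G_i) within ``cluster``: sum of R(G_i : G_j) over the other members."""
    values = R.values if isinstance(R, RedundancyMatrix) else np.asarray(R)
    members = list(cluster)
    if i not in members:
        raise ValueError("attribute must belong to the cluster")
    return float(sum(values[i, j] for j in members if j != i))
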