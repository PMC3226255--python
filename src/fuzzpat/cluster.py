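"""Mixed-mode attribute clustering (k-modes over the redundancy matrix).

Attributes (genes) are partitioned into k disjoint clusters.  Where
k-means summarizes a cluster by its centroid, this algorithm summarizes
it by its *mode*: the member with the highest multiple interdependence
redundancy MR, i.e. the most representative gene.  Iteration alternates

  assign: each attribute joins the cluster whose mode it is most
          redundant with (max R to the mode);
  update: each cluster's mode becomes the member with maximal MR.

Model selection over k maximizes SR, the sum of the modes' MR across
clusters.  Runs are restarted from seeded random mode sets and the best
SR iterate is kept, so the returned SR dominates every intermediate one.

Tie-breaking is deterministic throughout: assignment ties go to the
lowest cluster index, mode ties to the lowest attribute index, and SR
ties (within 1e-12) to the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import MixedModeTable
from .interdependence import RedundancyMatrix, redundancy_matrix

__all__ = ["AttributeClustering", "kmodes_cluster", "select_k", "AttributeClusterer"]

_SR_TOL = 1e-12


@dataclass
class AttributeClustering:
    """A disjoint, exhaustive partition of attribute indices with modes."""

    clusters: list[list[int]]
    modes: list[int]
    sr: float
    per_cluster_mr: list[float]
    attribute_names: list[str]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if seen & set(c):
                raise ValueError("clusters must be pairwise disjoint")
            seen |= set(c)
        if seen != set(range(len(self.attribute_names))):
            raise ValueError("clusters must cover every attribute exactly once")
        for mode, c in zip(self.modes, self.clusters):
            if mode not in c:
                raise ValueError("each mode must belong to its own cluster")

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def mode_names(self) -> list[str]:
        return [self.attribute_names[m] for m in self.modes]

    def labels(self) -> np.ndarray:
        lab = np.empty(len(self.attribute_names), dtype=np.intp)
        for r, c in enumerate(self.clusters):
            lab[c] = r
        return lab

    def cluster_of(self, attribute: int) -> int:
        return int(self.labels()[attribute])

    def to_dict(self) -> dict:
        return {
            "clusters": [list(map(int, c)) for c in self.clusters],
            "modes": list(map(int, self.modes)),
            "sr": float(self.sr),
            "per_cluster_mr": [float(v) for v in self.per_cluster_mr],
            "attribute_names": self.attribute_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AttributeClustering":
        return cls(
            [list(c) for c in d["clusters"]],
            list(d["modes"]),
            float(d["sr"]),
            [float(v) for v in d["per_cluster_mr"]],
            list(d["attribute_names"]),
        )


def _mode_and_mr(values: np.ndarray, members: np.ndarray) -> tuple[int, float]:
    """Member with maximal MR (ties -> lowest index) and its MR."""
    members = np.sort(members)
    sub = values[np.ix_(members, members)]
    mr = sub.sum(axis=1) - np.diag(sub)
    best = int(np.argmax(mr))  # argmax returns the first (lowest-index) max
    return int(members[best]), float(mr[best])


def _score(values: np.ndarray, assign: np.ndarray, k: int) -> tuple[list[int], list[float], float]:
    modes, mrs = [], []
    for r in range(k):
        members = np.where(assign == r)[0]
        mode, mr = _mode_and_mr(values, members)
        modes.append(mode)
        mrs.append(mr)
    return modes, mrs, float(sum(mrs))


def kmodes_cluster(
    R: RedundancyMatrix,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> AttributeClustering:
    """One seeded k-modes run; returns the best-SR iterate encountered."""
    values = R.values
    n = R.n_attributes
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    modes = list(rng.choice(n, size=k, replace=False))
    assign = None
    best: tuple[float, np.ndarray, list[int], list[float]] | None = None
    for _ in range(max_iter):
        sim = values[:, modes]
        new = np.asarray(np.argmax(sim, axis=1), dtype=np.intp)  # ties -> lowest cluster
        for r, mode in enumerate(modes):
            new[mode] = r  # a mode always stays in its own cluster
        # repair empty clusters with the attribute least similar to any mode
        for r in range(k):
            if not np.any(new == r):
                counts = np.bincount(new, minlength=k)
                movable = np.where(counts[new] > 1)[0]
                worst = movable[int(np.argmin(sim[movable].max(axis=1)))]
                new[worst] = r
                modes[r] = int(worst)
        if assign is not None and np.array_equal(new, assign):
            break
        assign = new
        modes, mrs, sr = _score(values, assign, k)
        if best is None or sr > best[0] + _SR_TOL:
            best = (sr, assign.copy(), list(modes), list(mrs))
    sr, assign, modes, mrs = best
    clusters = [sorted(np.where(assign == r)[0].tolist()) for r in range(k)]
    return AttributeClustering(clusters, modes, sr, mrs, R.attribute_names)


def select_k(
    R: RedundancyMatrix,
    k_min: int = 2,
    k_max: int | None = None,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 100,
) -> AttributeClustering:
    """Best clustering over ``k in [k_min, k_max]`` by SR maximization.

    Each k gets ``restarts`` seeded runs; the globally best SR wins, with
    ties (within 1e-12) resolved toward smaller k (parsimony).
    """
    n = R.n_attributes
    if k_max is None:
        k_max = min(n - 1, 10) if n > 1 else 1
    if not 1 <= k_min <= k_max <= n:
        raise ValueError("need 1 <= k_min <= k_max <= number of attributes")
    best: AttributeClustering | None = None
    for k in range(k_min, k_max + 1):
        for r in range(restarts):
            rng = np.random.default_rng([seed, k, r])
            cand = kmodes_cluster(R, k, rng, max_iter=max_iter)
            if best is None or cand.sr > best.sr + _SR_TOL:
                best = cand
    return best


class AttributeClusterer(BaseEstimator):
    """Scikit-learn style attribute (gene) clusterer with mode selection.

    ``fit`` computes the pairwise interdependence-redundancy matrix of
    the input attributes and partitions them by k-modes; ``transform``
    reduces a table to its cluster modes (representative-gene selection).

    Parameters
    ----------
    alpha : int, default 3
        Minimum data points per contingency-table cell for the bin-count
        rule.
    k : int or None
        Fixed number of clusters; ``None`` searches ``k_min..k_max`` by
        SR maximization.
    k_min, k_max : search range; ``k_max=None`` means ``min(N - 1, 10)``.
    restarts : seeded k-modes restarts per k.
    max_iter : iteration cap per run.
    random_state : base seed for mode initialization.

    Attributes
    ----------
    redundancy_ : RedundancyMatrix
    clustering_ : AttributeClustering
    k_ : selected number of clusters
    labels_ : cluster index per attribute
    modes_, mode_names_ : cluster modes (indices / attribute names)
    mode_mr_ : each mode's MR within its cluster
    sr_ : sum of the modes' MR (the model-selection objective)
    """

    def __init__(
        self,
        alpha: int = 3,
        k: int | None = None,
        k_min: int = 2,
        k_max: int | None = None,
        restarts: int = 10,
        max_iter: int = 100,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.restarts = restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def _as_table(self, X) -> MixedModeTable:
        if isinstance(X, MixedModeTable):
            return X
        if isinstance(X, pd.DataFrame):
            return MixedModeTable.from_dataframe(X.copy())
        arr = np.asarray(X, dtype=float)
        df = pd.DataFrame(arr, columns=[f"X{i}" for i in range(arr.shape[1])])
        return MixedModeTable.from_dataframe(df)

    def fit(self, X, y=None) -> "AttributeClusterer":
        table = self._as_table(X)
        self.redundancy_ = redundancy_matrix(table, alpha=self.alpha)
        if self.k is not None:
            best = None
            for r in range(self.restarts):
                rng = np.random.default_rng([self.random_state, self.k, r])
                cand = kmodes_cluster(self.redundancy_, self.k, rng, max_iter=self.max_iter)
                if best is None or cand.sr > best.sr + _SR_TOL:
                    best = cand
            self.clustering_ = best
        else:
            self.clustering_ = select_k(
                self.redundancy_,
                k_min=self.k_min,
                k_max=self.k_max,
                restarts=self.restarts,
                seed=self.random_state,
                max_iter=self.max_iter,
            )
        self.k_ = self.clustering_.k
        self.labels_ = self.clustering_.labels()
        self.modes_ = list(self.clustering_.modes)
        self.mode_names_ = self.clustering_.mode_names
        self.mode_mr_ = list(self.clustering_.per_cluster_mr)
        self.sr_ = self.clustering_.sr
        return self

    def transform(self, X):
        """Select the mode (representative) attributes of a table."""
        if not hasattr(self, "clustering_"):
            raise RuntimeError("fit before transform")
        if isinstance(X, MixedModeTable):
            return X.values[self.mode_names_]
        if isinstance(X, pd.DataFrame):
            return X[self.mode_names_]
        return np.asarray(X)[:, self.modes_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.mode_names_, dtype=object)

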