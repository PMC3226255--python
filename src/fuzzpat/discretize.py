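"""Mode-driven discretization of continuous attributes, per fuzzy cluster.

Within each (fuzzy) attribute cluster the mode plays the role of a class
variable:

* the mode itself, if continuous, is cut into three maximum-entropy
  (equal-frequency) intervals labelled L / N / H; a categorical mode
  simply keeps its symbols;
* every other continuous member is discretized *against* the mode by
  class-dependent optimal discretization (OCDD): candidate boundaries are
  the midpoints between consecutive distinct values, and the boundary set
  maximizing the interdependence redundancy R(discretized values : mode
  states) wins, searching every interval count from 2 up to
  ``max_intervals`` with ties resolved toward fewer intervals.

Because clusters are fuzzy, an attribute can appear in several cluster
event tables, each time discretized against a different mode and carrying
its membership weight in that cluster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import AttributeClustering
from .data import DiscreteCodes, IntervalScheme, MixedModeTable
from .fuzzify import FuzzyMembership
from .interdependence import categorical_codes

__all__ = [
    "discretize_mode",
    "ocdd",
    "ClusterEventTable",
    "build_cluster_event_tables",
]

_TOL = 1e-12
MODE_LABELS_3 = ("L", "N", "H")


def _generic_labels(q: int) -> tuple[str, ...]:
    return tuple(f"I{j + 1}" for j in range(q))


def discretize_mode(values: np.ndarray, n_intervals: int = 3, attribute: str = "") -> IntervalScheme:
    """Equal-frequency cuts: the maximum-entropy partition of an empirical
    distribution into ``n_intervals`` intervals.

    Cut-points are placed strictly between distinct observed values
    (midpoints), so tied values sit entirely in the lower interval and
    counts stay as equal as the ties permit.  Three intervals get the
    expression-state labels L / N / H, any other count generic I1..In.
    """
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    if n_intervals > len(distinct):
        raise ValueError("more intervals than distinct values")
    n = len(values)
    sv = np.sort(values)
    # positions (in the sorted array) where the value changes; a cut can
    # only sit between two distinct-value blocks
    boundaries = np.flatnonzero(np.diff(sv)) + 1
    cuts: list[float] = []
    for j in range(1, n_intervals):
        ideal = j * n / n_intervals
        dist = np.abs(boundaries - ideal)
        # ties toward the larger boundary: the lower interval absorbs ties
        b = boundaries[len(dist) - 1 - int(np.argmin(dist[::-1]))]
        cuts.append((sv[b - 1] + sv[b]) / 2.0)
    cuts_arr = np.unique(np.asarray(cuts))
    labels = MODE_LABELS_3 if len(cuts_arr) + 1 == 3 else _generic_labels(len(cuts_arr) + 1)
    return IntervalScheme(attribute, cuts_arr, labels)


def _partition_redundancy(rows: np.ndarray) -> float:
    """R = I/H of a q x c contingency-count table (rows = intervals)."""
    return float(_batched_redundancy(rows[None, :, :])[0])


def _batched_redundancy(tables: np.ndarray) -> np.ndarray:
    """R = I/H for a (B, q, c) stack of contingency-count tables."""
    totals = tables.sum(axis=(1, 2), keepdims=True)
    p = tables / totals
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        indep = px * py
        ilog = np.where(p > 0, p * np.log2(np.where(p > 0, p / np.where(indep > 0, indep, 1.0), 1.0)), 0.0)
    h = -plogp.sum(axis=(1, 2))
    i = ilog.sum(axis=(1, 2))
    return np.where(h > 0, i / np.where(h > 0, h, 1.0), 0.0)


def _candidate_cuts(values: np.ndarray, max_candidates: int | None) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    if max_candidates is not None and len(mids) > max_candidates:
        idx = np.unique(np.linspace(0, len(mids) - 1, max_candidates).round().astype(int))
        mids = mids[idx]
    return mids


def ocdd(
    values: np.ndarray,
    class_codes: DiscreteCodes,
    max_intervals: int = 3,
    max_candidates: int | None = 256,
    attribute: str = "",
) -> IntervalScheme:
    """Class-dependent optimal discretization against a discrete class.

    Searches, for every interval count q in 2..``max_intervals``, the cut
    set over the candidate boundaries (midpoints between consecutive
    distinct values, quantile-thinned to ``max_candidates`` when the
    attribute has very many distinct values) that maximizes
    R(discretized values : class); the globally best R wins, ties going
    to fewer intervals.  Fewer than two distinct values yield a
    single-interval passthrough scheme.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(class_codes):
        raise ValueError("values and class codes must have equal length")
    if max_intervals < 2:
        raise ValueError("max_intervals must be >= 2")
    if len(np.unique(values)) < 2:
        return IntervalScheme(attribute, np.array([]), _generic_labels(1))

    cand = _candidate_cuts(values, max_candidates)
    order = np.argsort(values, kind="stable")
    y = class_codes.codes[order]
    v_sorted = values[order]
    c = class_codes.m
    onehot = np.zeros((len(y), c))
    onehot[np.arange(len(y)), y] = 1.0
    prefix = np.vstack([np.zeros(c), np.cumsum(onehot, axis=0)])  # prefix[i] = counts of first i
    # number of values below each candidate cut
    below = np.searchsorted(v_sorted, cand, side="left")

    best_r = -np.inf
    best_cuts: tuple[int, ...] = ()
    n_cand = len(cand)
    for q in range(2, max_intervals + 1):
        if q - 1 > n_cand:
            break
        if q == 2:
            tables = np.stack(
                [prefix[below], prefix[-1][None, :] - prefix[below]], axis=1
            )
            rs = _batched_redundancy(tables)
            a = int(np.argmax(rs))
            if rs[a] > best_r + _TOL:
                best_r, best_cuts = float(rs[a]), (a,)
        elif q == 3:
            for a in range(n_cand - 1):
                rest = np.arange(a + 1, n_cand)
                row0 = np.broadcast_to(prefix[below[a]], (len(rest), c))
                row1 = prefix[below[rest]] - prefix[below[a]]
                row2 = prefix[-1][None, :] - prefix[below[rest]]
                rs = _batched_redundancy(np.stack([row0, row1, row2], axis=1))
                b = int(np.argmax(rs))
                if rs[b] > best_r + _TOL:
                    best_r, best_cuts = float(rs[b]), (a, int(rest[b]))
        else:
            # general case: batched evaluation over boundary combinations
            combos = np.array(list(itertools.combinations(range(n_cand), q - 1)))
            for chunk in np.array_split(combos, max(1, len(combos) // 4096)):
                bounds = np.concatenate(
                    [
                        np.zeros((len(chunk), 1), dtype=int),
                        below[chunk],
                        np.full((len(chunk), 1), len(y)),
                    ],
                    axis=1,
                )
                tables = np.diff(prefix[bounds], axis=1)
                rs = _batched_redundancy(tables)
                b = int(np.argmax(rs))
                if rs[b] > best_r + _TOL:
                    best_r, best_cuts = float(rs[b]), tuple(int(x) for x in chunk[b])
    cuts = cand[list(best_cuts)]
    return IntervalScheme(attribute, cuts, _generic_labels(len(cuts) + 1))


@dataclass
class ClusterEventTable:
    """Event labels of one fuzzy cluster's members, mode-discretized.

    ``events`` holds one symbol per (sample, member); continuous members
    carry an :class:`IntervalScheme`, categorical members pass through
    (scheme ``None``).  ``membership_weight`` records each member's fuzzy
    membership in this cluster.
    """

    cluster_id: int
    mode: str
    member_attributes: list[str]
    schemes: dict[str, IntervalScheme | None]
    events: pd.DataFrame
    membership_weight: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.events.columns) != list(self.member_attributes):
            raise ValueError("event columns must match member attributes")
        if self.mode not in self.member_attributes:
            raise ValueError("the mode must be a member of its own cluster")

    @property
    def n_samples(self) -> int:
        return len(self.events)

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "mode": self.mode,
            "member_attributes": self.member_attributes,
            "schemes": {
                a: (s.to_dict() if s is not None else None) for a, s in self.schemes.items()
            },
            "membership_weight": self.membership_weight,
            "events": {a: self.events[a].tolist() for a in self.events.columns},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterEventTable":
        members = list(d["member_attributes"])
        return cls(
            d["cluster_id"],
            d["mode"],
            members,
            {
                a: (IntervalScheme.from_dict(s) if s is not None else None)
                for a, s in d["schemes"].items()
            },
            pd.DataFrame({a: d["events"][a] for a in members}, columns=members),
            dict(d.get("membership_weight", {})),
        )


def _apply_schemes(
    table: MixedModeTable,
    members: list[str],
    schemes: dict[str, IntervalScheme | None],
) -> pd.DataFrame:
    cols = {}
    for name in members:
        scheme = schemes[name]
        if scheme is None:
            cols[name] = table.values[name].astype(str).to_numpy()
        else:
            cols[name] = scheme.assign(table.column(name))
    return pd.DataFrame(cols, columns=members)


def build_cluster_event_tables(
    table: MixedModeTable,
    clustering: AttributeClustering,
    membership: FuzzyMembership,
    tau: float = 0.003,
    max_intervals: int = 3,
    max_candidates: int | None = 256,
) -> list[ClusterEventTable]:
    """Discretize every fuzzy cluster's members against its mode.

    Cluster r's members are the attributes with mu_r >= ``tau``.  The
    mode, if continuous, gets the 3-state L/N/H maximum-entropy scheme
    (never re-discretized by OCDD within its own cluster); every other
    continuous member is discretized by :func:`ocdd` against the mode's
    states; categorical members pass through unchanged.
    """
    names = clustering.attribute_names
    if names != table.attribute_names:
        raise ValueError("table and clustering describe different attributes")
    out: list[ClusterEventTable] = []
    for r in range(clustering.k):
        mode_idx = clustering.modes[r]
        mode_name = names[mode_idx]
        member_idx = membership.members_at(r, tau)
        if mode_idx not in member_idx:
            raise ValueError(
                f"tau={tau} excludes cluster {r}'s own mode {mode_name!r}; lower tau"
            )
        members = [names[i] for i in sorted(member_idx)]
        schemes: dict[str, IntervalScheme | None] = {}
        if table.is_continuous(mode_name):
            mode_scheme = discretize_mode(table.column(mode_name), 3, attribute=mode_name)
            schemes[mode_name] = mode_scheme
            mode_codes = DiscreteCodes(
                mode_scheme.assign_codes(table.column(mode_name)), mode_scheme.n_intervals
            )
        else:
            schemes[mode_name] = None
            mode_codes = categorical_codes(table.column(mode_name))
        for name in members:
            if name == mode_name:
                continue
            if table.is_continuous(name):
                schemes[name] = ocdd(
                    table.column(name),
                    mode_codes,
                    max_intervals=max_intervals,
                    max_candidates=max_candidates,
                    attribute=name,
                )
            else:
                schemes[name] = None
        events = _apply_schemes(table, members, schemes)
        weights = {names[i]: float(membership.mu[i, r]) for i in sorted(member_idx)}
        out.append(ClusterEventTable(r, mode_name, members, schemes, events, weights))
    return out
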