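"""Discovery of statistically significant high-order event associations.

A *primary event* is one (attribute, interval/value) assertion.  A
pattern is a set of two or more primary events from distinct attributes
whose observed co-occurrence count deviates significantly from the
independence expectation.  Significance is judged by the adjusted
residual

    d = (o - e) / sqrt(v),    e = n * prod(p_i),    v = e * prod(1 - p_i)

where the p_i are the events' marginal probabilities; for a pair of
events this reduces exactly to the classical adjusted (standardized)
residual of a two-way contingency table, and d is asymptotically
standard normal under independence, so |d| >= 1.96 marks 95% two-sided
significance.  Candidates grow level-wise over attribute combinations;
a candidate is only scored when its independence expectation is at
least ``min_expected`` (validity of the normal approximation).

Patterns with d < 0 (significant under-representation) are retained in
the output with their sign; rule mining uses only positive associations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .discretize import ClusterEventTable

__all__ = [
    "AdjustedResidual",
    "adjusted_residual",
    "Pattern",
    "discover_patterns",
    "merge_patterns",
    "pattern_confidences",
]

_CUT_DECIMALS = 9


class AdjustedResidual(NamedTuple):
    d: float
    degenerate: bool


def adjusted_residual(observed: int, marginal_probs, n: int) -> AdjustedResidual:
    """Adjusted residual of an event set against the independence model.

    Degenerate when the variance vanishes (some marginal probability is
    1): the residual is then reported as 0 with the flag set.
    """
    p = np.asarray(marginal_probs, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("marginal probabilities must lie in (0, 1]")
    if observed > n:
        raise ValueError("observed count cannot exceed the sample size")
    e = n * float(np.prod(p))
    v = e * float(np.prod(1.0 - p))
    if v <= 0.0:
        return AdjustedResidual(0.0, True)
    return AdjustedResidual((observed - e) / math.sqrt(v), False)


@dataclass(frozen=True)
class Pattern:
    """A significant event association.

    ``events`` are (attribute, label) pairs over distinct attributes,
    stored sorted.  ``cuts`` pins down the interval schemes behind the
    labels so that patterns from different fuzzy clusters can be compared
    for identity.  ``confidences`` are optional post-hoc per-class
    fractions of the matching samples.
    """

    events: tuple[tuple[str, str], ...]
    observed: int
    expected: float
    residual: float
    source_clusters: tuple[int, ...]
    cuts: tuple[tuple[str, tuple[float, ...]], ...] = ()
    confidences: tuple[tuple[str, float], ...] | None = None

    @property
    def order(self) -> int:
        return len(self.events)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.events)

    def identity(self) -> tuple:
        """Merge key: events plus cut-points rounded to 1e-9."""
        rounded = tuple(
            (a, tuple(round(c, _CUT_DECIMALS) for c in cs)) for a, cs in self.cuts
        )
        return (self.events, rounded)

    def to_dict(self) -> dict:
        return {
            "events": [list(ev) for ev in self.events],
            "observed": self.observed,
            "expected": self.expected,
            "residual": self.residual,
            "order": self.order,
            "source_clusters": list(self.source_clusters),
            "cuts": {a: list(cs) for a, cs in self.cuts},
            "confidences": dict(self.confidences) if self.confidences is not None else None,
        }


def _event_columns(evt: ClusterEventTable) -> dict[str, dict[str, np.ndarray]]:
    """Per attribute: label -> boolean match mask."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for name in evt.member_attributes:
        col = evt.events[name].to_numpy()
        out[name] = {lab: col == lab for lab in pd.unique(col)}
    return out


def _scheme_cuts(evt: ClusterEventTable, attrs: tuple[str, ...]) -> tuple:
    cuts = []
    for a in attrs:
        scheme = evt.schemes.get(a)
        if scheme is not None:
            cuts.append((a, tuple(float(c) for c in scheme.cuts)))
    return tuple(cuts)


def discover_patterns(
    evt: ClusterEventTable,
    min_order: int = 2,
    max_order: int = 4,
    d_threshold: float = 1.96,
    min_expected: float = 3.0,
) -> list[Pattern]:
    """Level-wise search for significant event associations in one table.

    Extensions always draw events from attributes beyond the pattern's
    last one (each combination is generated once); growth is pruned below
    unobserved candidates, whose extensions are all unobserved as well.
    Output is sorted by |d| descending, ties broken lexicographically on
    the events.
    """
    if min_order < 2:
        raise ValueError("min_order must be >= 2")
    if d_threshold <= 0:
        raise ValueError("d_threshold must be positive")
    n = evt.n_samples
    attrs = list(evt.member_attributes)
    if max_order > len(attrs):
        max_order = len(attrs)
    masks = _event_columns(evt)
    probs = {
        (a, lab): float(mask.sum()) / n for a, labs in masks.items() for lab, mask in labs.items()
    }

    found: list[Pattern] = []
    # frontier entries: (events, mask, observed, attr index of last event)
    frontier: list[tuple[tuple[tuple[str, str], ...], np.ndarray, int]] = []
    for ai, a in enumerate(attrs):
        for lab, mask in masks[a].items():
            frontier.append((((a, lab),), mask, ai))
    for order in range(2, max_order + 1):
        nxt = []
        for events, mask, last in frontier:
            parent_obs = int(mask.sum())
            if parent_obs == 0:
                continue  # anti-monotone support: extensions stay unobserved
            for ai in range(last + 1, len(attrs)):
                a = attrs[ai]
                for lab, emask in masks[a].items():
                    new_events = events + ((a, lab),)
                    new_mask = mask & emask
                    o = int(new_mask.sum())
                    assert o <= parent_obs  # support never grows along an extension
                    if order >= min_order:
                        p = [probs[ev] for ev in new_events]
                        e = n * float(np.prod(p))
                        if e >= min_expected:
                            res = adjusted_residual(o, p, n)
                            if not res.degenerate and abs(res.d) >= d_threshold:
                                found.append(
                                    Pattern(
                                        tuple(sorted(new_events)),
                                        o,
                                        e,
                                        res.d,
                                        (evt.cluster_id,),
                                        _scheme_cuts(evt, tuple(a for a, _ in new_events)),
                                    )
                                )
                    if order < max_order:
                        nxt.append((new_events, new_mask, ai))
        frontier = nxt
    found.sort(key=lambda pat: (-abs(pat.residual), pat.events))
    return found


def merge_patterns(per_cluster: list[list[Pattern]]) -> list[Pattern]:
    """Collapse duplicates rediscovered in several fuzzy clusters.

    Two patterns are the same when their events match and the interval
    cut-points behind every label agree to 1e-9; the instance with the
    largest |d| is kept and the provenance (all source clusters) merged.
    """
    best: dict[tuple, Pattern] = {}
    for patterns in per_cluster:
        for pat in patterns:
            key = pat.identity()
            prev = best.get(key)
            if prev is None:
                best[key] = pat
            else:
                keep = pat if abs(pat.residual) > abs(prev.residual) else prev
                provenance = tuple(sorted(set(prev.source_clusters) | set(pat.source_clusters)))
                best[key] = Pattern(
                    keep.events,
                    keep.observed,
                    keep.expected,
                    keep.residual,
                    provenance,
                    keep.cuts,
                    keep.confidences,
                )
    out = list(best.values())
    out.sort(key=lambda pat: (-abs(pat.residual), pat.events))
    return out


def pattern_confidences(
    patterns: list[Pattern],
    event_tables: list[ClusterEventTable],
    class_labels: pd.Series,
) -> list[Pattern]:
    """Attach post-hoc per-class confidences Conf(P -> c) to patterns.

    For each pattern, the fraction of the samples matching its events
    that belong to each class.  Purely an evaluation aid: labels play no
    role in discovery.
    """
    y = np.asarray(class_labels.astype(str))
    by_cluster = {t.cluster_id: t for t in event_tables}
    out = []
    for pat in patterns:
        evt = by_cluster[pat.source_clusters[0]]
        mask = np.ones(evt.n_samples, dtype=bool)
        for a, lab in pat.events:
            mask &= evt.events[a].to_numpy() == lab
        total = int(mask.sum())
        conf = tuple(
            (cls, float((y[mask] == cls).sum()) / total if total else 0.0)
            for cls in sorted(pd.unique(y))
        )
        out.append(
            Pattern(
                pat.events, pat.observed, pat.expected, pat.residual,
                pat.source_clusters, pat.cuts, conf,
            )
        )
    return out
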