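"""Weight-of-evidence rules and classification.

Rules are mined exactly like patterns, with the class attribute appended
as one more event: an antecedent (a set of interval/value events) joined
to a class consequent is kept when the class-conditioned association is
significantly over-represented (positive adjusted residual above the
threshold).  Each rule carries a weight of evidence

    WofE = log2[ P(antecedent | class = c) / P(antecedent | class != c) ]

with Laplace smoothing (+1 on the matching counts, +#classes on the
conditioning totals) so the weight stays finite.  Positive values
support c.  A sample is classified by summing, per class, the WofE of
the rules it matches — preferring higher-order rules and skipping any
rule whose antecedent is a subset of an already-counted one — and taking
the argmax, with ties resolved toward the larger prior.

The evaluation protocol is honest by construction: clustering,
fuzzification and discretization never see the labels; labels enter only
here, at rule scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cluster import AttributeClusterer
from .data import MixedModeTable
from .discretize import ClusterEventTable, build_cluster_event_tables
from .fuzzify import fuzzy_memberships
from .patterns import adjusted_residual

__all__ = ["Rule", "weight_of_evidence", "mine_rules", "classify", "WofEClassifier"]


@dataclass(frozen=True)
class Rule:
    """if {antecedent events} then {consequent class}, weighted by WofE."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: str
    wofe: float
    support: int
    confidence: float
    residual: float
    source_cluster: int

    @property
    def order(self) -> int:
        return len(self.antecedent)

    def to_dict(self) -> dict:
        return {
            "antecedent": [list(ev) for ev in self.antecedent],
            "consequent": self.consequent,
            "wofe": self.wofe,
            "support": self.support,
            "confidence": self.confidence,
            "residual": self.residual,
            "source_cluster": self.source_cluster,
        }


def weight_of_evidence(match_mask: np.ndarray, y: np.ndarray, class_value: str) -> float:
    """Smoothed log2 likelihood ratio of an antecedent for/against a class."""
    y = np.asarray(y).astype(str)
    classes = np.unique(y)
    if class_value not in classes:
        raise ValueError(f"class {class_value!r} absent from the data")
    k = len(classes)
    in_c = y == class_value
    num = (int((match_mask & in_c).sum()) + 1) / (int(in_c.sum()) + k)
    den = (int((match_mask & ~in_c).sum()) + 1) / (int((~in_c).sum()) + k)
    return math.log2(num / den)


def _match_mask(evt: ClusterEventTable, antecedent) -> np.ndarray:
    mask = np.ones(evt.n_samples, dtype=bool)
    for a, lab in antecedent:
        mask &= evt.events[a].to_numpy() == lab
    return mask


def mine_rules(
    event_tables: list[ClusterEventTable],
    class_labels: pd.Series,
    min_order: int = 1,
    max_order: int = 3,
    d_threshold: float = 1.96,
    min_expected: float = 3.0,
) -> list[Rule]:
    """Mine class-supporting rules from the cluster event tables.

    The class is treated as one more event appended to the antecedent;
    a rule is retained when that joined association has adjusted residual
    >= ``d_threshold`` (positive: over-representation only).  Duplicate
    antecedent/consequent pairs across fuzzy clusters keep the instance
    with the largest residual.
    """
    y = np.asarray(class_labels.astype(str))
    n = len(y)
    class_probs = {c: float((y == c).sum()) / n for c in np.unique(y)}
    best: dict[tuple, Rule] = {}
    for evt in event_tables:
        attrs = list(evt.member_attributes)
        masks = {
            a: {lab: evt.events[a].to_numpy() == lab for lab in pd.unique(evt.events[a])}
            for a in attrs
        }
        probs = {
            (a, lab): float(m.sum()) / n for a, labs in masks.items() for lab, m in labs.items()
        }
        frontier = [(((a, lab),), m, ai) for ai, a in enumerate(attrs) for lab, m in masks[a].items()]
        for order in range(1, max_order + 1):
            nxt = []
            for events, mask, last in frontier:
                o_ant = int(mask.sum())
                if o_ant == 0:
                    continue
                if order >= min_order:
                    for cls, pc in class_probs.items():
                        p = [probs[ev] for ev in events] + [pc]
                        e = n * float(np.prod(p))
                        if e < min_expected:
                            continue
                        o = int((mask & (y == cls)).sum())
                        res = adjusted_residual(o, p, n)
                        if res.degenerate or res.d < d_threshold:
                            continue
                        rule = Rule(
                            tuple(sorted(events)),
                            cls,
                            weight_of_evidence(mask, y, cls),
                            o_ant,
                            o / o_ant,
                            res.d,
                            evt.cluster_id,
                        )
                        key = (rule.antecedent, cls)
                        prev = best.get(key)
                        if prev is None or rule.residual > prev.residual:
                            best[key] = rule
                if order < max_order:
                    for ai in range(last + 1, len(attrs)):
                        for lab, em in masks[attrs[ai]].items():
                            nxt.append((events + ((attrs[ai], lab),), mask & em, ai))
            frontier = nxt
    rules = list(best.values())
    rules.sort(key=lambda r: (-r.wofe, r.antecedent))
    return rules


def classify(
    sample_events: dict[int, dict[str, str]],
    rules: list[Rule],
    class_priors: dict[str, float],
    assume_sorted: bool = False,
) -> tuple[str, dict[str, float], bool]:
    """Classify one sample from its per-cluster event labels.

    ``sample_events[cluster][attribute]`` is the sample's label under
    that cluster's scheme.  Returns (class, per-class evidence totals,
    matched-anything flag).  Evidence per class sums matched rules' WofE,
    visiting higher-order rules first and skipping a rule whose
    antecedent is a subset of an already-counted antecedent for that
    class.  No matching rule at all falls back to the majority class
    with zero evidence.
    """
    if not rules:
        raise ValueError("rule list is empty")
    totals = {c: 0.0 for c in class_priors}
    counted: dict[str, list[set]] = {c: [] for c in class_priors}
    matched_any = False
    if not assume_sorted:
        rules = sorted(rules, key=lambda r: (-r.order, -abs(r.wofe)))
    for rule in rules:
        events = sample_events.get(rule.source_cluster, {})
        if any(events.get(a) != lab for a, lab in rule.antecedent):
            continue
        ant = set(rule.antecedent)
        if any(ant <= seen for seen in counted[rule.consequent]):
            continue
        totals[rule.consequent] = totals.get(rule.consequent, 0.0) + rule.wofe
        counted[rule.consequent].append(ant)
        matched_any = True
    if not matched_any:
        majority = max(class_priors, key=lambda c: (class_priors[c], c))
        return majority, totals, False
    winner = max(totals, key=lambda c: (totals[c], class_priors.get(c, 0.0), c))
    return winner, totals, True


class WofEClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end unsupervised-preprocessing, rule-based classifier.

    ``fit(X, y)`` runs the label-free pipeline on X — attribute
    clustering, fuzzification, mode-driven discretization — and only then
    joins ``y`` to mine weight-of-evidence rules.  ``predict`` maps new
    samples through the fitted interval schemes and sums rule evidence.

    Parameters mirror the pipeline stages; see the pipeline module for
    their meaning.  Fitted attributes: ``clusterer_``, ``membership_``,
    ``event_tables_``, ``rules_``, ``classes_``, ``class_priors_``.
    """

    def __init__(
        self,
        alpha: int = 3,
        k: int | None = None,
        k_min: int = 2,
        k_max: int | None = None,
        restarts: int = 10,
        max_iter: int = 100,
        f: float = 1.5,
        tau: float = 0.003,
        max_intervals: int = 3,
        max_candidates: int | None = 256,
        d_threshold: float = 1.96,
        min_expected: float = 3.0,
        max_order: int = 3,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.k = k
        self.k_min = k_min
        self.k_max = k_max
        self.restarts = restarts
        self.max_iter = max_iter
        self.f = f
        self.tau = tau
        self.max_intervals = max_intervals
        self.max_candidates = max_candidates
        self.d_threshold = d_threshold
        self.min_expected = min_expected
        self.max_order = max_order
        self.random_state = random_state

    def _as_table(self, X) -> MixedModeTable:
        if isinstance(X, MixedModeTable):
            return X
        if isinstance(X, pd.DataFrame):
            return MixedModeTable.from_dataframe(X.copy())
        arr = np.asarray(X, dtype=float)
        return MixedModeTable.from_dataframe(
            pd.DataFrame(arr, columns=[f"X{i}" for i in range(arr.shape[1])])
        )

    def fit(self, X, y) -> "WofEClassifier":
        table = self._as_table(X)
        y = pd.Series(np.asarray(y)).astype(str)
        if len(y) != table.n_samples:
            raise ValueError("X and y length mismatch")
        self.clusterer_ = AttributeClusterer(
            alpha=self.alpha, k=self.k, k_min=self.k_min, k_max=self.k_max,
            restarts=self.restarts, max_iter=self.max_iter,
            random_state=self.random_state,
        ).fit(table)
        self.membership_ = fuzzy_memberships(
            self.clusterer_.redundancy_, self.clusterer_.clustering_, f=self.f
        )
        self.event_tables_ = build_cluster_event_tables(
            table, self.clusterer_.clustering_, self.membership_,
            tau=self.tau, max_intervals=self.max_intervals,
            max_candidates=self.max_candidates,
        )
        self.rules_ = mine_rules(
            self.event_tables_, y,
            max_order=self.max_order, d_threshold=self.d_threshold,
            min_expected=self.min_expected,
        )
        self.classes_ = np.unique(np.asarray(y))
        n = len(y)
        self.class_priors_ = {c: float((y == c).sum()) / n for c in self.classes_}
        return self

    def _sample_events(self, table: MixedModeTable) -> list[dict[int, dict[str, str]]]:
        per_cluster: dict[int, pd.DataFrame] = {}
        for evt in self.event_tables_:
            cols = {}
            for a in evt.member_attributes:
                scheme = evt.schemes[a]
                if scheme is None:
                    cols[a] = table.values[a].astype(str).to_numpy()
                else:
                    cols[a] = scheme.assign(table.column(a))
            per_cluster[evt.cluster_id] = pd.DataFrame(cols)
        out = []
        for i in range(table.n_samples):
            out.append(
                {cid: df.iloc[i].to_dict() for cid, df in per_cluster.items()}
            )
        return out

    def predict(self, X) -> np.ndarray:
        table = self._as_table(X)
        ordered = sorted(self.rules_, key=lambda r: (-r.order, -abs(r.wofe)))
        preds = [
            classify(ev, ordered, self.class_priors_, assume_sorted=True)[0]
            for ev in self._sample_events(table)
        ]
        return np.asarray(preds)

    def decision_totals(self, X) -> pd.DataFrame:
        """Per-class summed weight of evidence for every sample."""
        table = self._as_table(X)
        rows = [classify(ev, self.rules_, self.class_priors_)[1] for ev in self._sample_events(table)]
        return pd.DataFrame(rows)
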