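"""Fuzzification of a crisp attribute clustering.

A crisp partition assigns each gene to exactly one cluster, so an
association pattern whose genes straddle a cluster boundary can never be
seen by per-cluster pattern discovery.  Fuzzification gives every gene a
degree of membership in *every* cluster, derived from its redundancy with
each cluster's mode:

    mu_r(G_i) = R(G_i : G^r)^(1/(f-1)) / sum_c R(G_i : G^c)^(1/(f-1))

with fuzzification parameter f > 1.  At f = 2 the exponent is 1 and the
memberships are the linearly normalized redundancies; as f -> 1+ each row
sharpens toward the indicator of the best-matching mode; as f -> infinity
rows flatten toward the uniform 1/k.  Rows always sum to one.  A gene
with zero redundancy to every mode (only possible for a constant
attribute) falls back to the uniform row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import AttributeClustering
from .interdependence import RedundancyMatrix

__all__ = ["FuzzyMembership", "fuzzy_memberships", "crisp_memberships"]


@dataclass
class FuzzyMembership:
    """Attributes x clusters membership matrix; rows sum to 1."""

    mu: np.ndarray
    f: float
    clustering: AttributeClustering

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        n = len(self.clustering.attribute_names)
        if self.mu.shape != (n, self.clustering.k):
            raise ValueError("membership matrix shape must be attributes x clusters")

    def membership(self, attribute: str, cluster: int) -> float:
        i = self.clustering.attribute_names.index(attribute)
        return float(self.mu[i, cluster])

    def members_at(self, cluster: int, tau: float) -> list[int]:
        """Attribute indices whose membership in ``cluster`` is >= tau."""
        return np.where(self.mu[:, cluster] >= tau)[0].tolist()

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "f": float(self.f),
            "clustering": self.clustering.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyMembership":
        return cls(np.asarray(d["mu"]), d["f"], AttributeClustering.from_dict(d["clustering"]))


def fuzzy_memberships(
    R: RedundancyMatrix,
    clustering: AttributeClustering,
    f: float = 1.5,
) -> FuzzyMembership:
    """Per-attribute fuzzy memberships over all clusters (see module docs)."""
    if not f > 1:
        raise ValueError("fuzzification parameter f must be > 1")
    sim = R.values[:, clustering.modes]  # attributes x k, entries in [0, 1]
    with np.errstate(divide="ignore"):
        weights = np.power(sim, 1.0 / (f - 1.0))
    totals = weights.sum(axis=1, keepdims=True)
    k = clustering.k
    mu = np.where(totals > 0, weights / np.where(totals > 0, totals, 1.0), 1.0 / k)
    return FuzzyMembership(mu, f, clustering)


def crisp_memberships(clustering: AttributeClustering) -> FuzzyMembership:
    """The f -> 1+ (winner-take-all) limit: the crisp indicator matrix.

    Useful as the no-fuzzification baseline when demonstrating that
    patterns straddling crisp cluster boundaries require fuzzification.
    """
    n = len(clustering.attribute_names)
    mu = np.zeros((n, clustering.k))
    for r, members in enumerate(clustering.clusters):
        mu[members, r] = 1.0
    return FuzzyMembership(mu, 1.0 + 1e-12, clustering)
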