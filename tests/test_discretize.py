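"""Mode discretization and class-dependent optimal discretization (OCDD)."""

import itertools
import math

import numpy as np
import pytest

import fuzzpat as fp
from fuzzpat.data import DiscreteCodes
from fuzzpat.discretize import _partition_redundancy


class TestDiscretizeMode:
    def test_exact_tertiles(self):
        s = fp.discretize_mode(np.arange(1.0, 10.0), 3)
        np.testing.assert_allclose(s.cuts, [3.5, 6.5])
        assert s.labels == ("L", "N", "H")
        codes = s.assign_codes(np.arange(1.0, 10.0))
        assert np.bincount(codes).tolist() == [3, 3, 3]

    def test_lower_interval_absorbs_ties(self):
        v = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0])
        s = fp.discretize_mode(v, 2)
        np.testing.assert_allclose(s.cuts, [2.5])
        assert np.bincount(s.assign_codes(v), minlength=2).tolist() == [6, 1]

    def test_near_maximum_entropy_on_uniform(self, rng):
        v = rng.uniform(size=1800)
        s = fp.discretize_mode(v, 3)
        p = np.bincount(s.assign_codes(v)) / len(v)
        entropy = -(p * np.log2(p)).sum()
        assert entropy > math.log2(3) - 1e-3

    def test_generic_labels_beyond_three(self):
        s = fp.discretize_mode(np.arange(8.0), 4)
        assert s.labels == ("I1", "I2", "I3", "I4")

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError):
            fp.discretize_mode(np.array([1.0, 1.0, 2.0]), 3)


def naive_table_r(counts: np.ndarray) -> float:
    """I/H of a count table by explicit double loops (independent oracle)."""
    n = counts.sum()
    I = H = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / n
            if p == 0:
                continue
            px = counts[i, :].sum() / n
            py = counts[:, j].sum() / n
            I += p * math.log2(p / (px * py))
            H -= p * math.log2(p)
    return I / H if H > 0 else 0.0


def exhaustive_ocdd(values, class_codes, max_intervals):
    """Brute-force best R over every subset of midpoint boundaries."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2
    best = -np.inf
    best_cuts = ()
    for q in range(2, max_intervals + 1):
        for combo in itertools.combinations(mids, q - 1):
            codes = np.searchsorted(np.array(combo), values, side="right")
            counts = np.zeros((q, class_codes.m))
            for c, y in zip(codes, class_codes.codes):
                counts[c, y] += 1
            r = naive_table_r(counts)
            if r > best + 1e-12:
                best, best_cuts = r, combo
    return best, best_cuts


class TestOcdd:
    def test_perfect_separation_single_cut(self):
        v = np.arange(1.0, 11.0)
        y = DiscreteCodes((v >= 5).astype(int), 2)
        s = fp.ocdd(v, y, max_intervals=3)
        assert len(s.cuts) == 1
        assert 4.0 < s.cuts[0] < 5.0
        codes = DiscreteCodes(s.assign_codes(v), s.n_intervals)
        r = fp.mutual_information(codes, y) / fp.joint_entropy(codes, y)
        assert r == pytest.approx(1.0)

    def test_matches_exhaustive_search(self, rng):
        """DP equals brute force over all boundary subsets, <= 12 values."""
        for trial in range(10):
            v = rng.choice(np.linspace(0, 1, 12), size=40, replace=True)
            y = DiscreteCodes(rng.integers(0, 3, size=40), 3)
            s = fp.ocdd(v, y, max_intervals=3, max_candidates=None)
            codes = DiscreteCodes(
                np.searchsorted(s.cuts, v, side="right"), s.n_intervals
            )
            counts = np.zeros((s.n_intervals, 3))
            for c, cls in zip(codes.codes, y.codes):
                counts[c, cls] += 1
            r_impl = _partition_redundancy(counts)
            r_oracle, _ = exhaustive_ocdd(v, y, 3)
            assert r_impl == pytest.approx(r_oracle, abs=1e-12)

    def test_widening_search_never_hurts(self, rng):
        """A larger max_intervals searches a superset of cut sets."""
        v = rng.uniform(size=60)
        y = DiscreteCodes((v > 0.5).astype(int), 2)

        def best_r(max_intervals):
            s = fp.ocdd(v, y, max_intervals=max_intervals, max_candidates=None)
            codes = np.searchsorted(s.cuts, v, side="right")
            counts = np.zeros((s.n_intervals, 2))
            for c, cls in zip(codes, y.codes):
                counts[c, cls] += 1
            return _partition_redundancy(counts)

        assert best_r(3) >= best_r(2) - 1e-12

    def test_shuffled_labels_fall_below_null(self, rng):
        v = rng.uniform(size=80)
        y_dep = DiscreteCodes((v > 0.5).astype(int), 2)
        y_perm = DiscreteCodes(rng.permutation(y_dep.codes), 2)

        def best_r(y):
            s = fp.ocdd(v, y, max_intervals=3)
            codes = np.searchsorted(s.cuts, v, side="right")
            counts = np.zeros((s.n_intervals, 2))
            for c, cls in zip(codes, y.codes):
                counts[c, cls] += 1
            return _partition_redundancy(counts)

        nulls = [
            best_r(DiscreteCodes(rng.permutation(y_dep.codes), 2)) for _ in range(30)
        ]
        assert best_r(y_perm) < best_r(y_dep)
        assert best_r(y_dep) > np.percentile(nulls, 95)

    def test_single_distinct_value_passthrough(self):
        s = fp.ocdd(np.full(5, 2.0), DiscreteCodes(np.zeros(5, dtype=int), 1))
        assert s.n_intervals == 1 and len(s.cuts) == 0

    def test_recovers_generator_breakpoints(self, synthetic_dataset):
        """A14 discretized against A13's states finds cuts near 0.3, 0.6."""
        t = synthetic_dataset.table
        mode = fp.discretize_mode(t.column("A13"), 3, attribute="A13")
        codes = DiscreteCodes(mode.assign_codes(t.column("A13")), 3)
        s = fp.ocdd(t.column("A14"), codes, max_intervals=3, attribute="A14")
        assert len(s.cuts) == 2
        assert abs(s.cuts[0] - 0.3) < 0.02 and abs(s.cuts[1] - 0.6) < 0.02


@pytest.fixture(scope="module")
def fitted(synthetic_dataset):
    t = synthetic_dataset.table.without_class()
    est = fp.AttributeClusterer(k=3, restarts=3, random_state=0).fit(t)
    mu = fp.fuzzy_memberships(est.redundancy_, est.clustering_, f=1.5)
    return t, est, mu


class TestBuildClusterEventTables:
    def test_tau_zero_includes_every_attribute(self, fitted):
        t, est, mu = fitted
        tables = fp.build_cluster_event_tables(t, est.clustering_, mu, tau=0.0)
        assert all(len(evt.member_attributes) == 20 for evt in tables)

    def test_crisp_limit_reduces_to_crisp_clusters(self, fitted):
        t, est, mu = fitted
        crisp = fp.crisp_memberships(est.clustering_)
        tables = fp.build_cluster_event_tables(t, est.clustering_, crisp, tau=0.5)
        for evt, members in zip(tables, est.clustering_.clusters):
            expected = sorted(est.clustering_.attribute_names[i] for i in members)
            assert sorted(evt.member_attributes) == expected

    def test_mode_scheme_is_three_state(self, fitted):
        t, est, mu = fitted
        tables = fp.build_cluster_event_tables(t, est.clustering_, mu, tau=0.003)
        for evt in tables:
            scheme = evt.schemes[evt.mode]
            if scheme is not None:  # continuous mode
                assert scheme.labels == ("L", "N", "H")
            labels = set(evt.events[evt.mode])
            assert labels <= ({"L", "N", "H"} | {"T", "F", "X", "Y", "Z"})

    def test_every_sample_maps_to_exactly_one_interval(self, fitted):
        t, est, mu = fitted
        tables = fp.build_cluster_event_tables(t, est.clustering_, mu, tau=0.003)
        for evt in tables:
            assert not evt.events.isna().any().any()
            assert len(evt.events) == t.n_samples

    def test_excessive_tau_raises(self, fitted):
        t, est, mu = fitted
        with pytest.raises(ValueError):
            fp.build_cluster_event_tables(t, est.clustering_, mu, tau=1.01)
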