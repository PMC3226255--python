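"""Mutual information, joint entropy and the redundancy measure R."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fuzzpat as fp
from fuzzpat.data import DiscreteCodes, MixedModeTable
from fuzzpat.interdependence import categorical_codes


def naive_information(counts: np.ndarray) -> tuple[float, float]:
    """Double-loop plug-in I and H from a count table (the oracle)."""
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
    return I, H


def codes_from_counts(counts: np.ndarray) -> tuple[DiscreteCodes, DiscreteCodes]:
    xs, ys = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            xs += [i] * counts[i, j]
            ys += [j] * counts[i, j]
    return DiscreteCodes(np.array(xs), counts.shape[0]), DiscreteCodes(np.array(ys), counts.shape[1])


class TestChooseBinCount:
    def test_slow_growth_with_sample_size(self):
        # ln(1800/3) ~ 6.4 -> 6 bins; ln(62/3) ~ 3.03 -> 3 bins
        assert fp.choose_bin_count(1800, 3) == 6
        assert fp.choose_bin_count(62, 3) == 3

    def test_floor_at_two(self):
        assert fp.choose_bin_count(4, 1) == 2

    def test_alpha_exceeding_sample_size_raises(self):
        with pytest.raises(ValueError):
            fp.choose_bin_count(3, 5)


class TestBinContinuous:
    def test_median_split(self):
        codes = fp.bin_continuous(np.arange(1, 11, dtype=float), 2)
        assert np.bincount(codes.codes).tolist() == [5, 5]

    def test_constant_vector_collapses(self):
        codes = fp.bin_continuous(np.full(10, 3.0), 2)
        assert codes.m == 1

    def test_quantile_bins_are_balanced(self, rng):
        v = rng.uniform(size=1800)
        codes = fp.bin_continuous(v, 6)
        counts = np.bincount(codes.codes)
        assert counts.max() - counts.min() <= 1

    def test_more_bins_than_values_raises(self):
        with pytest.raises(ValueError):
            fp.bin_continuous(np.array([1.0, 2.0]), 3)


class TestInformationMeasures:
    def test_identical_binary_variables(self):
        x = DiscreteCodes(np.tile([0, 1], 50), 2)
        assert fp.mutual_information(x, x) == pytest.approx(1.0)
        assert fp.joint_entropy(x, x) == pytest.approx(1.0)

    def test_independent_by_construction(self):
        x, y = codes_from_counts(np.array([[25, 25], [25, 25]]))
        assert fp.mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)
        assert fp.joint_entropy(x, y) == pytest.approx(2.0)

    def test_length_mismatch_raises(self):
        x = DiscreteCodes(np.array([0, 1]), 2)
        y = DiscreteCodes(np.array([0]), 1)
        with pytest.raises(ValueError):
            fp.mutual_information(x, y)

    @given(
        st.integers(2, 5).flatmap(
            lambda ncols: st.lists(
                st.lists(st.integers(0, 30), min_size=ncols, max_size=ncols),
                min_size=2,
                max_size=5,
            )
        ).filter(lambda rows: sum(map(sum, rows)) > 0)
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_naive_oracle_on_small_tables(self, rows):
        counts = np.array(rows)
        x, y = codes_from_counts(counts)
        I_o, H_o = naive_information(counts)
        assert fp.mutual_information(x, y) == pytest.approx(I_o, abs=1e-12)
        assert fp.joint_entropy(x, y) == pytest.approx(H_o, abs=1e-12)
        assert -1e-12 <= I_o <= H_o + 1e-12

    def test_merging_bins_never_increases_information(self, rng):
        """Coarsening one margin cannot raise I (data-processing)."""
        for _ in range(20):
            counts = rng.integers(0, 20, size=(3, 3))
            if counts.sum() == 0:
                continue
            x, y = codes_from_counts(counts)
            merged = counts.copy()
            merged[1] += merged[2]
            xm, ym = codes_from_counts(merged[:2])
            assert fp.mutual_information(xm, ym) <= fp.mutual_information(x, y) + 1e-9


class TestRedundancy:
    def test_self_redundancy_is_one(self, small_mixed_table):
        assert fp.redundancy(small_mixed_table, 0, 0) == pytest.approx(1.0)

    def test_symmetry_and_bounds_on_random_tables(self, rng):
        df = pd.DataFrame(
            {
                "c1": rng.choice(["a", "b", "c"], 120),
                "g1": rng.uniform(size=120),
                "g2": rng.uniform(size=120),
            }
        )
        t = MixedModeTable.from_dataframe(df)
        R = fp.redundancy_matrix(t, alpha=3)
        np.testing.assert_array_equal(R.values, R.values.T)
        assert np.all(R.values >= 0) and np.all(R.values <= 1 + 1e-12)
        assert np.allclose(np.diag(R.values), 1.0)

    def test_constant_attribute_has_zero_redundancy(self):
        df = pd.DataFrame({"g1": [1.0, 1.0, 1.0, 1.0], "g2": [1.0, 2.0, 3.0, 4.0]})
        t = MixedModeTable.from_dataframe(df)
        R = fp.redundancy_matrix(t, alpha=1)
        assert R.values[0, 0] == 0.0 and R.values[0, 1] == 0.0

    def test_independent_attributes_near_zero(self, rng):
        n = 1800
        df = pd.DataFrame({"g1": rng.uniform(size=n), "g2": rng.uniform(size=n)})
        t = MixedModeTable.from_dataframe(df)
        assert fp.redundancy(t, 0, 1, alpha=3) < 0.05

    def test_dependent_attribute_beats_permutation_null(self, rng):
        """A range-coupled pair scores far above its permutation null."""
        n = 600
        flag = rng.choice(["T", "F"], n)
        dep = np.where(flag == "T", rng.uniform(0, 0.5, n), rng.uniform(0.5, 1, n))
        t = MixedModeTable.from_dataframe(pd.DataFrame({"a": flag, "b": dep}))
        observed = fp.redundancy(t, 0, 1, alpha=3)
        null = []
        for _ in range(100):
            tp = MixedModeTable.from_dataframe(
                pd.DataFrame({"a": rng.permutation(flag), "b": dep})
            )
            null.append(fp.redundancy(tp, 0, 1, alpha=3))
        assert observed > np.percentile(null, 99)


class TestMultipleRedundancy:
    def test_singleton_cluster_is_zero(self):
        R = fp.RedundancyMatrix(np.eye(3), ["a", "b", "c"], 3, 2)
        assert fp.multiple_redundancy(R, 0, [0]) == 0.0

    def test_closed_form_on_uniform_cluster(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        R = fp.RedundancyMatrix(vals, ["a", "b", "c"], 3, 2)
        for i in range(3):
            assert fp.multiple_redundancy(R, i, [0, 1, 2]) == pytest.approx(1.0)

    def test_membership_required(self):
        R = fp.RedundancyMatrix(np.eye(2), ["a", "b"], 3, 2)
        with pytest.raises(ValueError):
            fp.multiple_redundancy(R, 0, [1])
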