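"""Filter rankers checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tristage.filters import (
    ContingencyTable,
    RankedList,
    chi_square_statistic,
    discretize,
    mutual_information_bits,
    rank_chi_square,
    rank_mutual_information,
    rank_relieff,
    rank_xvariance,
)
from conftest import make_dataset


# -- independent oracles -----------------------------------------------------

def mi_oracle(bins, codes):
    """Plug-in mutual information by direct summation over observed cells."""
    n = len(bins)
    total = 0.0
    for b in np.unique(bins):
        for c in np.unique(codes):
            p_joint = np.mean((bins == b) & (codes == c))
            if p_joint > 0:
                p_b = np.mean(bins == b)
                p_c = np.mean(codes == c)
                total += p_joint * np.log2(p_joint / (p_b * p_c))
    return total


def chi2_oracle(counts):
    """Cell-by-cell (O-E)^2/E with expectations from the margins."""
    counts = np.asarray(counts, dtype=float)
    z = counts.sum()
    total = 0.0
    for m in range(counts.shape[0]):
        for n in range(counts.shape[1]):
            e = counts[m].sum() * counts[:, n].sum() / z
            if e > 0:
                total += (counts[m, n] - e) ** 2 / e
    return total


def xv_oracle(column, labels):
    """Naive sum of per-class sample variances (n-1 denominator)."""
    total = 0.0
    for cls in np.unique(labels):
        vals = column[labels == cls]
        if len(vals) >= 2:
            total += float(np.var(vals, ddof=1))
    return total


def random_discrete_dataset(rng):
    n = int(rng.integers(8, 51))
    n_classes = int(rng.integers(2, 5))
    n_feats = int(rng.integers(2, 7))
    bins = int(rng.integers(2, 7))
    while True:
        y = rng.integers(0, n_classes, size=n)
        if len(np.unique(y)) == n_classes and np.bincount(y).min() >= 2:
            break
    X = rng.integers(0, bins, size=(n, n_feats)).astype(float)
    return make_dataset(X, [f"c{v}" for v in y]), bins


class TestDiscretize:
    def test_median_split(self):
        np.testing.assert_array_equal(discretize(np.array([1, 2, 3, 4]), 2), [0, 0, 1, 1])

    def test_constant_column(self):
        np.testing.assert_array_equal(discretize(np.full(5, 3.3), 4), np.zeros(5))

    def test_equal_frequency_three_bins(self):
        # sorted order 1,2 | 3,4 | 5,6
        np.testing.assert_array_equal(
            discretize(np.array([5, 1, 3, 2, 4, 6]), 3), [2, 0, 1, 0, 1, 2]
        )

    def test_empty_column_errors(self):
        with pytest.raises(ValueError):
            discretize(np.array([]), 2)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 1000), st.integers(2, 8))
    def test_bin_ids_contiguous_and_ties_share_bins(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        col = rng.integers(0, 5, size=30).astype(float)
        codes = discretize(col, n_bins)
        assert set(codes) == set(range(codes.max() + 1))
        assert codes.max() + 1 <= n_bins
        for v in np.unique(col):
            assert len(set(codes[col == v])) == 1


class TestMutualInformation:
    def test_perfect_binary_feature_is_one_bit(self):
        y = ["A", "B"] * 10
        d = make_dataset(np.array([[0, 1] * 10], dtype=float).T, y)
        rl = rank_mutual_information(d, n_bins=2)
        assert rl.scores[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_feature_is_zero(self):
        # identical feature distribution within each class
        d = make_dataset(
            np.array([[1, 2, 1, 2, 1, 2, 1, 2]], dtype=float).T,
            ["A", "A", "B", "B", "A", "A", "B", "B"],
        )
        rl = rank_mutual_information(d, n_bins=2)
        assert rl.scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_plug_in_value_from_contingency(self):
        # joint counts [[2,1],[1,2]] over 6 samples
        bins = np.array([0, 0, 0, 1, 1, 1])
        codes = np.array([0, 0, 1, 0, 1, 1])
        table = ContingencyTable.from_codes(bins, codes)
        assert mutual_information_bits(table) == pytest.approx(
            mi_oracle(bins, codes), abs=1e-12
        )


class TestChiSquare:
    def test_diagonal_counts(self):
        table = ContingencyTable.from_codes(
            np.repeat([0, 1], 10), np.repeat([0, 1], 10)
        )
        assert chi_square_statistic(table) == pytest.approx(20.0)

    def test_proportional_counts_are_zero(self):
        bins = np.array([0] * 6 + [1] * 12)
        codes = np.array([0, 0, 0, 0, 1, 1] + [0] * 8 + [1] * 4)
        table = ContingencyTable.from_codes(bins, codes)
        assert chi_square_statistic(table) == pytest.approx(0.0, abs=1e-12)

    def test_matches_cellwise_oracle(self):
        counts = np.array([[3, 1], [2, 4]])
        bins = np.repeat([0, 0, 1, 1], [3, 1, 2, 4]) * 0
        bins = np.array([0] * 4 + [1] * 6)
        codes = np.array([0, 0, 0, 1, 0, 0, 1, 1, 1, 1])
        table = ContingencyTable.from_codes(bins, codes)
        np.testing.assert_array_equal(table.counts, counts)
        assert chi_square_statistic(table) == pytest.approx(
            chi2_oracle(counts), abs=1e-12
        )


class TestOracleEquivalence:
    def test_mi_and_chi2_match_brute_force_on_random_data(self):
        """Plug-in MI and chi-square agree with direct contingency-table
        evaluation on 120 random small discrete datasets."""
        rng = np.random.default_rng(2024)
        for _ in range(120):
            d, bins = random_discrete_dataset(rng)
            mi = rank_mutual_information(d, n_bins=bins)
            cs = rank_chi_square(d, n_bins=bins)
            _, codes = np.unique(d.labels, return_inverse=True)
            for j in range(d.n_features):
                binned = discretize(d.features[:, j], bins)
                assert mi.scores[j] == pytest.approx(
                    mi_oracle(binned, codes), abs=1e-10
                )
                table = ContingencyTable.from_codes(binned, codes)
                assert cs.scores[j] == pytest.approx(
                    chi2_oracle(table.counts), abs=1e-10
                )

    def test_xvariance_matches_naive_sum(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            d, _ = random_discrete_dataset(rng)
            xv = rank_xvariance(d)
            for j in range(d.n_features):
                assert xv.scores[j] == pytest.approx(
                    xv_oracle(d.features[:, j], d.labels), abs=1e-12
                )


class TestXvariance:
    def test_zero_within_class_variance(self):
        d = make_dataset([[0], [0], [1], [1]], ["A", "A", "B", "B"])
        assert rank_xvariance(d).scores[0] == 0.0

    def test_hand_computed_sum(self):
        d = make_dataset([[0], [2], [10], [14]], ["A", "A", "B", "B"])
        assert rank_xvariance(d).scores[0] == pytest.approx(10.0)

    def test_shift_invariance(self):
        d1 = make_dataset([[0.0], [2], [10], [14]], list("AABB"))
        d2 = make_dataset([[100.0], [102], [110], [114]], list("AABB"))
        assert rank_xvariance(d1).scores[0] == pytest.approx(
            rank_xvariance(d2).scores[0]
        )


class TestReliefF:
    def _clustered(self):
        # f0 separates two tight clusters by class; f1 is fixed noise
        f0 = np.array([0.0, 0.05, 0.1, 0.02, 0.08, 0.9, 0.95, 1.0, 0.92, 0.97])
        f1 = np.array([0.3, 0.9, 0.1, 0.7, 0.5, 0.2, 0.8, 0.4, 0.6, 0.05])
        y = ["A"] * 5 + ["B"] * 5
        return make_dataset(np.column_stack([f0, f1]), y)

    def test_constant_feature_weight_zero(self):
        d = make_dataset(
            np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)]),
            ["A"] * 5 + ["B"] * 5,
        )
        rl = rank_relieff(d, k_neighbors=2)
        assert rl.scores[0] == 0.0

    def test_separating_feature_beats_noise(self):
        rl = rank_relieff(self._clustered(), k_neighbors=2)
        assert rl.scores[0] > rl.scores[1]
        assert rl.order[0] == 0

    def test_duplicate_features_get_identical_weights(self):
        d0 = self._clustered()
        d = make_dataset(
            np.column_stack([d0.features[:, 0], d0.features[:, 0], d0.features[:, 1]]),
            d0.labels,
        )
        rl = rank_relieff(d, k_neighbors=2)
        assert rl.scores[0] == pytest.approx(rl.scores[1], abs=1e-12)

    def test_sample_permutation_invariance(self):
        d = self._clustered()
        perm = np.random.default_rng(3).permutation(d.n_samples)
        dp = make_dataset(d.features[perm], d.labels[perm])
        a = rank_relieff(d, k_neighbors=2).scores
        b = rank_relieff(dp, k_neighbors=2).scores
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_small_class_errors(self):
        d = make_dataset(np.random.default_rng(0).random((6, 2)), list("AABBBB"))
        with pytest.raises(ValueError, match="k_neighbors"):
            rank_relieff(d, k_neighbors=3)


class TestRankedList:
    def test_order_is_descending_permutation_with_index_ties(self):
        rl = RankedList.from_scores("XV", np.array([0.5, 0.9, 0.5, 0.1]))
        np.testing.assert_array_equal(rl.order, [1, 0, 2, 3])
        assert sorted(rl.order) == [0, 1, 2, 3]

    def test_tsv_export(self, tmp_path):
        import pandas as pd

        rl = RankedList.from_scores("MI", np.array([0.1, 0.7]))
        p = tmp_path / "r.tsv"
        rl.to_tsv(p, ["a", "b"])
        frame = pd.read_csv(p, sep="\t")
        assert list(frame.feature_name) == ["b", "a"]
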