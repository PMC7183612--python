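import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rareclust.consensus import (
    RepresentativeSet,
    WeightParams,
    collapse_representatives,
    connectivity_matrix,
    consensus_cluster,
    consensus_matrix,
    expand_and_flag,
    gini_weight,
    pair_weights,
    partition_consensus,
)
from rareclust.graph_cluster import Partition


def cell_level_consensus(gini, fano, params):
    """Brute-force application of the weighting formulas to all N cells."""
    x = gini.proportions[gini.labels]
    wtg = 1.0 - 1.0 / (1.0 + np.exp(-(x - params.mu) / params.s))
    wtg_pair = np.maximum.outer(wtg, wtg)
    wg = wtg_pair / (wtg_pair + params.f_const)
    mg = connectivity_matrix(gini.labels)
    mf = connectivity_matrix(fano.labels)
    return wg * mg + (1.0 - wg) * mf


class TestCollapse:
    def test_direct_tally(self):
        gini = Partition.from_labels([0, 0, 0, 1, 1], relabel_by_size=False)
        fano = Partition.from_labels([0, 0, 1, 1, 1], relabel_by_size=False)
        reps = collapse_representatives(gini, fano)
        assert reps.n == 3
        assert reps.pairs.tolist() == [[0, 0], [0, 1], [1, 1]]
        assert reps.multiplicity.tolist() == [2, 1, 2]
        assert reps.representative_cell.tolist() == [0, 2, 3]

    def test_identical_partitions_diagonal_pairs(self):
        labels = np.arange(6) % 3
        p = Partition.from_labels(labels)
        reps = collapse_representatives(p, p)
        assert reps.n == p.n_clusters

    def test_multiplicities_sum_to_n(self):
        rng = np.random.default_rng(17)
        gini = Partition.from_labels(rng.integers(0, 7, 1000))
        fano = Partition.from_labels(rng.integers(0, 5, 1000))
        reps = collapse_representatives(gini, fano)
        assert reps.multiplicity.sum() == 1000
        # every cell maps to the pair matching its own labels
        for i in [0, 13, 999]:
            pi = reps.cell_to_pair[i]
            assert reps.pairs[pi].tolist() == [gini.labels[i], fano.labels[i]]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            collapse_representatives(
                Partition.from_labels([0, 1]), Partition.from_labels([0, 1, 1])
            )


class TestConnectivity:
    def test_by_definition(self):
        np.testing.assert_array_equal(
            connectivity_matrix([0, 0, 1]),
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]],
        )

    def test_degenerate_cases(self):
        assert connectivity_matrix([2, 2, 2]).min() == 1  # all ones
        np.testing.assert_array_equal(connectivity_matrix([0, 1, 2]), np.eye(3))


class TestWeights:
    def test_logistic_midpoint_and_limits(self):
        p = WeightParams(mu=0.1, s=0.05, f_const=1.0)
        assert gini_weight(0.1, p) == pytest.approx(0.5, abs=1e-15)
        # one steepness step above the crossover: 1/(1+e)
        assert gini_weight(0.15, p) == pytest.approx(1 / (1 + np.e), abs=1e-12)
        # x -> 0+ approaches the supremum 1 (steep logistic)
        steep = WeightParams(mu=0.1, s=0.005, f_const=1.0)
        assert gini_weight(1e-9, steep) > 0.99

    def test_strictly_decreasing_in_proportion(self):
        p = WeightParams()
        xs = np.linspace(0.01, 1.0, 50)
        w = gini_weight(xs, p)
        assert (np.diff(w) < 0).all()

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            gini_weight(0.0, WeightParams())
        with pytest.raises(ValueError):
            gini_weight(1.2, WeightParams())

    def test_hand_example_max_and_normalization(self):
        # two reps with raw Gini weights 0.9 and 0.1, constant Fano weight 1:
        # pair weight = max = 0.9, normalized to 0.9/1.9
        p = WeightParams(mu=0.5, s=0.113728457747459, f_const=1.0)
        # proportions chosen so the logistic gives exactly 0.9 and 0.1:
        # w(x) = 0.9  <=>  x = mu - s*ln(9);  w = 0.1  <=>  x = mu + s*ln(9)
        x_hi = p.mu - p.s * np.log(9)
        assert gini_weight(x_hi, p) == pytest.approx(0.9, abs=1e-12)
        wtg = np.array([0.9, 0.1])
        wtg_pair = np.maximum.outer(wtg, wtg)
        wg = wtg_pair / (wtg_pair + p.f_const)
        assert wg[0, 1] == pytest.approx(0.9 / 1.9, abs=1e-12)

    def test_pair_weights_sum_to_one_and_symmetric(self):
        rng = np.random.default_rng(23)
        gini = Partition.from_labels(rng.integers(0, 4, 200))
        fano = Partition.from_labels(rng.integers(0, 3, 200))
        reps = collapse_representatives(gini, fano)
        wg, wf = pair_weights(reps, gini, WeightParams())
        np.testing.assert_allclose(wg + wf, 1.0, rtol=0, atol=1e-15)
        np.testing.assert_array_equal(wg, wg.T)
        assert (wg > 0).all() and (wg < 1).all()


class TestConsensusMatrix:
    def test_identical_partitions_reproduce_connectivity(self):
        labels = np.array([0, 0, 1, 2])
        m = connectivity_matrix(labels)
        rng = np.random.default_rng(2)
        wg = rng.uniform(0.2, 0.8, size=(4, 4))
        wg = (wg + wg.T) / 2
        mbar = consensus_matrix(m, m, wg, 1.0 - wg)
        np.testing.assert_allclose(mbar, m)

    def test_gini_only_agreement_weighted_entry(self):
        mg = np.ones((2, 2))
        mf = np.eye(2)
        wg = np.full((2, 2), 0.9 / 1.9)
        mbar = consensus_matrix(mg, mf, wg, 1.0 - wg)
        assert mbar[0, 1] == pytest.approx(0.9 / 1.9, abs=1e-12)
        np.testing.assert_allclose(np.diag(mbar), 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            consensus_matrix(
                np.ones((2, 2)), np.ones((3, 3)), np.ones((2, 2)),
                np.ones((2, 2)),
            )


class TestPartitionConsensus:
    def test_block_diagonal_recovered(self):
        mbar = np.zeros((6, 6))
        mbar[:3, :3] = 1
        mbar[3:, 3:] = 1
        labels = partition_consensus(mbar, k=2, seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equal_n_each_rep_separate(self):
        mbar = np.eye(5)
        labels = partition_consensus(mbar, k=5, seed=0)
        assert len(set(labels)) == 5

    def test_noisy_three_blocks_mostly_recovered(self):
        sizes = [10, 8, 6]
        truth = np.repeat([0, 1, 2], sizes)
        base = connectivity_matrix(truth)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            noisy = base.copy()
            flip = rng.random(base.shape) < 0.05
            flip = np.triu(flip, 1)
            flip = flip | flip.T
            noisy[flip] = 1 - noisy[flip]
            np.fill_diagonal(noisy, 1)
            labels = partition_consensus(noisy, k=3, seed=seed)
            if adjusted_rand_score(truth, labels) == 1.0:
                hits += 1
        assert hits > 10

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            partition_consensus(np.eye(4), k=5, seed=0)


class TestExpandAndFlag:
    def test_cells_inherit_and_sub_threshold_cluster_rare(self):
        # 200 cells: clusters of 199 and 1 -> 0.5% cluster is rare
        gini = Partition.from_labels([0] * 199 + [1])
        fano = Partition.from_labels([0] * 199 + [1])
        reps = collapse_representatives(gini, fano)
        cells, rare = expand_and_flag(
            np.array([0, 1]), reps, rare_threshold=0.01
        )
        assert cells.sizes.tolist() == [199, 1]
        assert rare.tolist() == [False, True]

    def test_cluster_at_exactly_one_percent_not_rare(self):
        # 1 of 100 cells: proportion exactly 0.01 -> strict rule says common
        gini = Partition.from_labels([0] * 99 + [1])
        reps = collapse_representatives(gini, gini)
        _, rare = expand_and_flag(np.array([0, 1]), reps, rare_threshold=0.01)
        assert not rare[1]
        # just above the boundary the same cluster is rare
        _, rare_above = expand_and_flag(
            np.array([0, 1]), reps, rare_threshold=0.0100001
        )
        assert rare_above[1]

    def test_sizes_partition_all_cells(self):
        rng = np.random.default_rng(8)
        gini = Partition.from_labels(rng.integers(0, 5, 500))
        fano = Partition.from_labels(rng.integers(0, 4, 500))
        reps = collapse_representatives(gini, fano)
        labels = rng.integers(0, 3, reps.n)
        cells, _ = expand_and_flag(labels, reps)
        assert cells.sizes.sum() == 500


class TestCollapseEquivalence:
    def test_expanded_consensus_matches_cell_level_bruteforce(self):
        """Collapsing to representatives must not change any pairwise value."""
        rng = np.random.default_rng(55)
        n = 300
        params = WeightParams()
        gini = Partition.from_labels(rng.integers(0, 6, n))
        fano = Partition.from_labels(rng.integers(0, 4, n))
        reps = collapse_representatives(gini, fano)
        mg = connectivity_matrix(reps.pairs[:, 0])
        mf = connectivity_matrix(reps.pairs[:, 1])
        wg, wf = pair_weights(reps, gini, params)
        mbar = consensus_matrix(mg, mf, wg, wf)
        expanded = mbar[np.ix_(reps.cell_to_pair, reps.cell_to_pair)]
        direct = cell_level_consensus(gini, fano, params)
        np.testing.assert_allclose(expanded, direct, atol=1e-12)

    def test_representative_choice_cannot_affect_weights(self):
        # weights depend only on cluster labels, constant within a pair
        rng = np.random.default_rng(56)
        gini = Partition.from_labels(rng.integers(0, 3, 50))
        fano = Partition.from_labels(rng.integers(0, 3, 50))
        reps = collapse_representatives(gini, fano)
        x = gini.proportions[gini.labels]
        for p_idx in range(reps.n):
            members = np.flatnonzero(reps.cell_to_pair == p_idx)
            assert np.unique(x[members]).size == 1
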