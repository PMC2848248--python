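"""Bayesian hierarchical clustering: marginals, tree construction, cutting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from srokit import bhc
from conftest import enumerate_set_partitions, partition_to_labels


class TestDmLogMarginal:
    def test_empty_matrix_has_probability_one(self):
        assert bhc.dm_log_marginal(np.empty((0, 4))) == 0.0

    def test_single_observation_uniform_predictive(self):
        assert bhc.dm_log_marginal([[0]]) == pytest.approx(math.log(1 / 3))

    def test_two_agreeing_and_disagreeing_rows(self):
        assert bhc.dm_log_marginal([[1], [1]]) == pytest.approx(math.log(1 / 6))
        assert bhc.dm_log_marginal([[1], [0]]) == pytest.approx(math.log(1 / 12))

    def test_columns_factorize(self):
        rows = np.array([[1, -1], [0, -1]])
        total = bhc.dm_log_marginal(rows)
        assert total == pytest.approx(
            bhc.dm_log_marginal(rows[:, :1]) + bhc.dm_log_marginal(rows[:, 1:])
        )

    @pytest.mark.parametrize("alpha", [(1, 1, 1), (0.5, 0.5, 0.5), (2, 1, 3)])
    @pytest.mark.parametrize("n,e", [(1, 1), (2, 1), (3, 2)])
    def test_normalizes_over_all_datasets(self, alpha, n, e):
        """Summing exp(marginal) over every possible dataset gives one."""
        total = sum(
            math.exp(bhc.dm_log_marginal(
                np.array(flat).reshape(n, e), alpha))
            for flat in itertools.product((-1, 0, 1), repeat=n * e)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bhc.dm_log_marginal([[2]])
        with pytest.raises(ValueError):
            bhc.dm_log_marginal([[0]], alpha=(1, 1))


class TestBuildAndCut:
    def test_single_item_tree_is_a_leaf_with_r_one(self):
        tree = bhc.build(np.array([[1, 0, -1]]))
        assert tree.root.r == 1.0
        part = bhc.cut(tree)
        assert part.n_clusters == 1

    def test_identical_rows_favor_the_merge(self):
        tree = bhc.build(np.zeros((2, 4), dtype=int))
        assert tree.root.r > 0.5
        assert bhc.cut(tree).n_clusters == 1

    def test_fully_disagreeing_rows_favor_the_split(self):
        data = np.vstack([np.ones(8, dtype=int), -np.ones(8, dtype=int)])
        tree = bhc.build(data)
        assert tree.root.r < 0.5
        part = bhc.cut(tree)
        assert part.n_clusters == 2

    def test_two_row_merge_posterior_matches_closed_form(self):
        """For n=2 the greedy step reduces to one closed-form r."""
        data = np.zeros((2, 4), dtype=int)
        h1 = bhc.dm_log_marginal(data)
        leaves = bhc.dm_log_marginal(data[:1]) * 2
        # pi = conc*Gamma(2) / (conc*Gamma(2) + conc^2) = 1/2 for conc=1
        expected = 0.5 * math.exp(h1) / (
            0.5 * math.exp(h1) + 0.5 * math.exp(leaves)
        )
        tree = bhc.build(data)
        assert tree.root.r == pytest.approx(expected, rel=1e-12)

    def test_planted_two_cluster_data_recovered(self):
        data = np.vstack([
            np.tile([1, 1, 1, 1, -1, -1, -1, -1], (3, 1)),
            np.tile([-1, -1, -1, -1, 1, 1, 1, 1], (3, 1)),
        ])
        part = bhc.cut(bhc.build(data))
        assert part.n_clusters == 2
        assert len(set(part.labels[:3])) == 1
        assert part.labels[0] != part.labels[3]

    def test_sibling_members_partition_the_parent(self):
        rng = np.random.default_rng(4)
        data = rng.integers(-1, 2, size=(6, 5))
        tree = bhc.build(data)
        for node in tree.nodes:
            if node.children is not None:
                left = tree.nodes[node.children[0]].members
                right = tree.nodes[node.children[1]].members
                assert set(left) & set(right) == set()
                assert tuple(sorted(left + right)) == node.members

    def test_merge_posteriors_are_probabilities(self):
        rng = np.random.default_rng(5)
        tree = bhc.build(rng.integers(-1, 2, size=(8, 6)))
        assert all(0.0 <= node.r <= 1.0 for node in tree.nodes)

    def test_permuting_items_permutes_the_partition(self):
        rng = np.random.default_rng(6)
        data = rng.integers(-1, 2, size=(7, 6))
        perm = rng.permutation(7)
        base = bhc.cut(bhc.build(data)).labels
        permuted = bhc.cut(bhc.build(data[perm])).labels
        # same co-clustering structure after undoing the permutation
        co_base = base[:, None] == base[None, :]
        inv = np.argsort(perm)
        co_perm = permuted[inv][:, None] == permuted[inv][None, :]
        assert np.array_equal(co_base, co_perm)

    def test_newick_rendering_contains_posteriors(self):
        tree = bhc.build(np.zeros((2, 2), dtype=int))
        text = tree.to_newick(labels=["a", "b"])
        assert text.startswith("(") and "[&r=" in text and text.endswith(";")


def test_greedy_tree_map_partition_near_exhaustive_optimum():
    """The best tree-consistent partition scores in the enumeration's top
    two nearly always, bounding what the greedy agglomeration loses
    against free enumeration of all set partitions."""
    rng = np.random.default_rng(12)
    cfg = bhc.BhcConfig()
    hits = 0
    n_trials = 60
    for _ in range(n_trials):
        data = rng.integers(-1, 2, size=(4, 4))
        part = bhc.cut_map(bhc.build(data, cfg))
        got = bhc.partition_log_score(data, part.labels, cfg)
        scores = sorted(
            (bhc.partition_log_score(data, partition_to_labels(blocks, 4), cfg)
             for blocks in enumerate_set_partitions(range(4))),
            reverse=True,
        )
        if got >= scores[1] - 1e-9:
            hits += 1
    assert hits / n_trials >= 0.95


def test_map_cut_never_scores_below_the_threshold_cut():
    """Both cuts are tree-consistent; the MAP cut maximizes the flat score
    over that space, so it dominates the threshold rule."""
    rng = np.random.default_rng(13)
    cfg = bhc.BhcConfig()
    for _ in range(40):
        data = rng.integers(-1, 2, size=(5, 4))
        tree = bhc.build(data, cfg)
        s_thresh = bhc.partition_log_score(data, bhc.cut(tree).labels, cfg)
        s_map = bhc.partition_log_score(data, bhc.cut_map(tree).labels, cfg)
        assert s_map >= s_thresh - 1e-12


def test_cuts_agree_on_clearly_separated_data():
    data = np.vstack([
        np.tile([1, 1, 1, 1, -1, -1, -1, -1], (3, 1)),
        np.tile([-1, -1, -1, -1, 1, 1, 1, 1], (3, 1)),
    ])
    tree = bhc.build(data)
    assert np.array_equal(bhc.cut(tree).labels, bhc.cut_map(tree).labels)


@given(st.integers(0, 2 ** 12 - 1))
def test_cut_blocks_cover_all_items_exactly_once(bits):
    data = np.array([(bits >> (2 * i)) % 3 - 1 for i in range(6)]).reshape(3, 2)
    part = bhc.cut(bhc.build(data))
    assert sorted(np.unique(part.labels)) == list(range(part.n_clusters))
    assert len(part.labels) == 3
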