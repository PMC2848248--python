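"""Distances, neighbour joining, rooting and group assignment."""

import dendropy
import numpy as np
import pytest

from srokit import phylo


def random_additive_tree(n_leaves, rng):
    """Random binary tree with positive branch lengths plus its exact
    leaf-to-leaf path-distance matrix (the oracle for NJ recovery)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels]
    pool = list(nodes)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = dendropy.Node()
        for idx in (j, i):  # pop larger index first
            child = pool.pop(idx)
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.1, 2.0))
        pool.append(parent)
    center = dendropy.Node()
    for child in pool:
        center.add_child(child)
        child.edge.length = float(rng.uniform(0.1, 2.0))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                mat[i, j] = pdm.distance(taxa.get_taxon(a), taxa.get_taxon(b))
    return tree, phylo.DistanceMatrix(labels=labels, matrix=mat)


def patristic(tree, labels):
    taxa = tree.taxon_namespace
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                mat[i, j] = pdm.distance(taxa.get_taxon(labels[i]),
                                         taxa.get_taxon(labels[j]))
    return mat


class TestPDistance:
    def test_identical_sequences_have_zero_distance(self):
        d = phylo.p_distance([("a", "ACDE"), ("b", "ACDE")])
        assert d.matrix[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        d = phylo.p_distance([("a", "ACDE"), ("b", "ACDF")])
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded_pairwise(self):
        d = phylo.p_distance([("a", "AC-E"), ("b", "ACDE")])
        assert d.matrix[0, 1] == 0.0

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            phylo.p_distance([("a", "--AA"), ("b", "AA--")])

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            phylo.p_distance([("a", "AAA"), ("b", "AA")])

    def test_poisson_correction_expands_distances(self):
        plain = phylo.p_distance([("a", "AAAA"), ("b", "AAAC")])
        corr = phylo.p_distance([("a", "AAAA"), ("b", "AAAC")],
                                poisson_correction=True)
        assert corr.matrix[0, 1] == pytest.approx(-np.log(0.75))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
        tree = phylo.neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_fewer_than_three_taxa_rejected(self):
        dm = phylo.DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            phylo.neighbor_joining(dm)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) as an additive matrix
        mat = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        dm = phylo.DistanceMatrix(list("ABCD"), mat)
        tree = phylo.neighbor_joining(dm)
        assert np.allclose(patristic(tree, list("ABCD")), mat, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        true_tree, dm = random_additive_tree(8, rng)
        nj = phylo.neighbor_joining(dm)
        assert np.allclose(patristic(nj, dm.labels), dm.matrix, atol=1e-9)
        # identical unrooted topology
        taxa = dendropy.TaxonNamespace(dm.labels)
        t1 = dendropy.Tree.get(data=phylo.tree_to_newick(true_tree),
                               schema="newick", taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=phylo.tree_to_newick(nj),
                               schema="newick", taxon_namespace=taxa)
        t1.encode_bipartitions(); t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_topology_agrees_with_independent_nj_on_noisy_matrix(self):
        """Cross-check against scikit-bio's neighbour joining."""
        import skbio

        rng = np.random.default_rng(10)
        _, dm = random_additive_tree(7, rng)
        noisy = dm.matrix + rng.uniform(0, 0.01, dm.matrix.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = phylo.neighbor_joining(phylo.DistanceMatrix(dm.labels, noisy))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
        taxa = dendropy.TaxonNamespace(dm.labels)
        t1 = dendropy.Tree.get(data=phylo.tree_to_newick(ours),
                               schema="newick", taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick",
                               taxon_namespace=taxa)
        t1.encode_bipartitions(); t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_equal_distances_resolve_deterministically(self):
        mat = np.ones((4, 4)) - np.eye(4)
        dm = phylo.DistanceMatrix(list("ABCD"), mat)
        a = phylo.tree_to_newick(phylo.neighbor_joining(dm))
        b = phylo.tree_to_newick(phylo.neighbor_joining(dm))
        assert a == b

    def test_newick_roundtrip_lossless(self):
        rng = np.random.default_rng(3)
        _, dm = random_additive_tree(6, rng)
        tree = phylo.neighbor_joining(dm)
        text = phylo.tree_to_newick(tree)
        back = phylo.tree_from_newick(text)
        assert phylo.tree_to_newick(back) == text


class TestRootAndGroup:
    def family_tree(self):
        text = "((out1:0.1,out2:0.1):0.5,((g1a:0.1,g1b:0.1):0.3,(g2a:0.1,g2b:0.1):0.3):0.2);"
        return dendropy.Tree.get(data=text, schema="newick")

    def test_leaves_inherit_their_reference_clade_group(self):
        tree = self.family_tree()
        _, groups = phylo.root_and_group(
            tree, ["out1", "out2"], {"g1a": "I", "g2a": "II"})
        assert groups["g1b"] == "I"
        assert groups["g2b"] == "II"

    def test_outgroup_leaves_unassigned(self):
        tree = self.family_tree()
        _, groups = phylo.root_and_group(tree, ["out1", "out2"], {"g1a": "I"})
        assert groups["out1"] == "unassigned"

    def test_no_references_leaves_all_unassigned(self):
        tree = self.family_tree()
        _, groups = phylo.root_and_group(tree, ["out1", "out2"], {})
        assert set(groups.values()) == {"unassigned"}

    def test_root_separates_outgroup_clade(self):
        tree = self.family_tree()
        rooted, _ = phylo.root_and_group(tree, ["out1", "out2"], {"g1a": "I"})
        children = rooted.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in c.leaf_iter()} for c in children]
        assert {"out1", "out2"} in sides

    def test_missing_outgroup_taxon_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            phylo.root_and_group(self.family_tree(), ["nope"], {})

    def test_nonmonophyletic_outgroup_warns(self):
        tree = self.family_tree()
        with pytest.warns(UserWarning, match="monophyletic"):
            phylo.root_and_group(tree, ["out1", "g1a"], {})

    def test_leaf_order_permutation_invariance(self):
        rng = np.random.default_rng(6)
        _, dm = random_additive_tree(6, rng)
        refs = {"t1": "I", "t4": "II"}
        perm = rng.permutation(6)
        labels_p = [dm.labels[i] for i in perm]
        mat_p = dm.matrix[np.ix_(perm, perm)]
        t_a = phylo.neighbor_joining(dm)
        t_b = phylo.neighbor_joining(phylo.DistanceMatrix(labels_p, mat_p))
        _, g_a = phylo.root_and_group(t_a, ["t0"], refs)
        _, g_b = phylo.root_and_group(t_b, ["t0"], refs)
        assert g_a == g_b
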