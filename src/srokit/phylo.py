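"""Distance-based phylogeny of PARP-domain alignments.

p-distances with pairwise gap deletion feed a neighbour-joining tree
(Saitou-Nei); the tree is rooted on the branch to a designated outgroup
(classical PARPs) and each remaining leaf inherits the phylogenetic group
(I or II) of the reference-containing clade it falls in.  Trees are held as
dendropy objects, so Newick I/O and rerooting use the standard machinery.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "neighbor_joining",
    "root_and_group",
    "tree_to_newick",
    "tree_from_newick",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match the label count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any():
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


def p_distance(
    msa: list[tuple[str, str]], poisson_correction: bool = False
) -> DistanceMatrix:
    """Pairwise p-distances over an alignment with pairwise gap deletion.

    For each sequence pair only columns where neither sequence has a gap are
    compared; the distance is mismatches / compared columns.  With
    ``poisson_correction`` the multiple-hit corrected -ln(1 - p) is returned
    instead.
    """
    labels = [rid for rid, _ in msa]
    seqs = [seq.upper() for _, seq in msa]
    if len(seqs) < 2:
        raise ValueError("at least two sequences are required")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    arr = np.array([list(s) for s in seqs])
    gap = (arr == "-") | (arr == ".")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            if not ok.any():
                raise ValueError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no "
                    "comparable columns"
                )
            p = (arr[i, ok] != arr[j, ok]).mean()
            if poisson_correction:
                if p >= 1.0:
                    raise ValueError("p-distance of 1 cannot be Poisson-corrected")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, matrix=d)


def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou-Nei neighbour joining.

    Recovers additive metrics exactly.  Ties in the Q-matrix minimization
    break towards the lowest (i, j) index pair in the current active-node
    ordering; negative branch-length estimates are clamped to zero with the
    deficit transferred to the sibling branch (their sum is preserved).
    Returns an unrooted dendropy tree (trifurcation at the seed node).
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dist.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False
    nodes = [dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in dist.labels]
    d = dist.matrix.astype(float).copy()
    active = list(range(n))
    store = {i: nodes[i] for i in range(n)}
    next_id = n
    dmat = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    def get(i, j):
        return 0.0 if i == j else dmat[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = get(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:
            bj, bi = bj + bi, 0.0
        if bj < 0:
            bi, bj = bi + bj, 0.0
        parent = dendropy.Node()
        ni, nj = store[i], store[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = bi
        nj.edge.length = bj
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dmat[(min(k, new), max(k, new))] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [new]
        store[new] = parent

    # connect the last three nodes to a central (seed) node
    i, j, k = active
    center = dendropy.Node()
    bi = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    bj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    bk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    for idx, length in ((i, bi), (j, bj), (k, bk)):
        node = store[idx]
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    tree.seed_node = center
    return tree


def root_and_group(
    tree: dendropy.Tree,
    outgroup: list[str],
    group_refs: dict[str, str] | None = None,
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Outgroup-root a tree and assign group I/II labels by clade membership.

    The root is placed on the branch separating the outgroup clade (the edge
    above the outgroup's most recent common ancestor, split at its
    midpoint).  A non-monophyletic outgroup triggers a warning and the MRCA
    edge is used regardless.  Each leaf outside the outgroup inherits the
    group of the smallest enclosing clade that contains reference leaves of
    a single group; leaves with no uniform reference clade are "unassigned".
    """
    group_refs = group_refs or {}
    rooted = tree.clone(depth=1)
    rooted.is_rooted = True
    leaf_labels = {lf.taxon.label for lf in rooted.leaf_node_iter()}
    missing = set(outgroup) - leaf_labels
    if missing:
        raise ValueError(f"outgroup taxa missing from tree: {sorted(missing)}")

    if leaf_labels - set(outgroup):
        mrca = rooted.mrca(taxon_labels=list(outgroup))
        in_clade = {lf.taxon.label for lf in mrca.leaf_iter()}
        if in_clade != set(outgroup):
            _warnings.warn(
                "outgroup is not monophyletic; rooting at its MRCA edge",
                stacklevel=2,
            )
        if mrca is not rooted.seed_node:
            edge = mrca.edge
            half = (edge.length or 0.0) / 2.0
            rooted.reroot_at_edge(edge, length1=half, length2=half,
                                  update_bipartitions=True)

    groups: dict[str, str] = {}
    for leaf in rooted.leaf_node_iter():
        label = leaf.taxon.label
        if label in outgroup:
            groups[label] = "unassigned"
            continue
        if label in group_refs:
            groups[label] = group_refs[label]
            continue
        assigned = "unassigned"
        node = leaf.parent_node
        while node is not None:
            refs = {
                group_refs[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in group_refs
            }
            if refs:
                if len(refs) == 1:
                    assigned = refs.pop()
                break
            node = node.parent_node
        groups[label] = assigned
    return rooted, groups


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tree_from_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
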