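"""Bayesian agglomerative hierarchical clustering of trinary regulation data.

Rows (genes, or experiments when clustering the other direction) carry one of
three regulation states per column.  Within a cluster each column is modelled
as a Dirichlet-multinomial over {down, none, up}, columns conditionally
independent given cluster membership.  Agglomeration follows the standard
Bayesian hierarchical clustering scheme: at each step the pair of subtrees
with the highest posterior probability of the "merged into one cluster"
hypothesis is joined, and the number of clusters falls out of cutting the
tree where that posterior drops below a threshold.

The cluster-tree prior uses a Dirichlet-process-style weight: a subtree over
n_k items receives prior mass pi_k = conc * Gamma(n_k) / d_k with
d_k = conc * Gamma(n_k) + d_left * d_right, leaves having d = conc.  The
merge posterior at node k is

    r_k = pi_k * p(D_k | H1) / p(D_k | T_k)

with p(D_k|T_k) = pi_k p(D_k|H1) + (1 - pi_k) p(D_l|T_l) p(D_r|T_r), all
evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BhcConfig",
    "BhcNode",
    "BhcTree",
    "Partition",
    "dm_log_marginal",
    "build",
    "cut",
    "cut_map",
    "partition_log_score",
]

_STATES = (-1, 0, 1)


@dataclass
class BhcConfig:
    """Hyperparameters of the clustering model.

    alpha : Dirichlet pseudocounts for (down, none, up); symmetric (1,1,1)
        by default.
    conc : concentration of the cluster-tree prior.
    cut_threshold : merge posterior below which a node is split when
        flattening the tree.
    """

    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    conc: float = 1.0
    cut_threshold: float = 0.5

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.alpha) or len(self.alpha) != 3:
            raise ValueError("alpha must be three positive pseudocounts")
        if self.conc <= 0:
            raise ValueError("conc must be positive")
        if not 0 < self.cut_threshold < 1:
            raise ValueError("cut_threshold must lie in (0, 1)")


@dataclass
class BhcNode:
    members: tuple[int, ...]
    children: tuple[int, int] | None
    counts: np.ndarray          # experiments x 3 state counts
    log_h1: float               # log p(D_k | H1), all members one cluster
    log_tree: float             # log p(D_k | T_k)
    log_d: float                # log d_k of the prior recursion
    log_pi: float               # log pi_k
    r: float                    # merge posterior; 1.0 at leaves by convention

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class BhcTree:
    """Merge dendrogram; ids 0..n-1 are leaves, the last node is the root."""

    nodes: list[BhcNode]
    n_items: int
    config: BhcConfig

    @property
    def root(self) -> BhcNode:
        return self.nodes[-1]

    def to_newick(self, labels: list[str] | None = None) -> str:
        """Newick rendering with merge posteriors as node comments."""
        labels = labels or [str(i) for i in range(self.n_items)]

        def render(idx: int) -> str:
            node = self.nodes[idx]
            if node.children is None:
                return labels[node.members[0]]
            left, right = node.children
            return f"({render(left)},{render(right)})[&r={node.r:.6f}]"

        return render(len(self.nodes) - 1) + ";"


@dataclass
class Partition:
    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.n_clusters != len(np.unique(self.labels)):
            raise ValueError("n_clusters inconsistent with labels")


def _state_counts(rows: np.ndarray) -> np.ndarray:
    """Per-column counts of the three states; rows is items x experiments."""
    rows = np.asarray(rows)
    if rows.ndim == 1:
        rows = rows[None, :]
    if not np.isin(rows, _STATES).all():
        raise ValueError("data entries must lie in {-1, 0, +1}")
    return np.stack([(rows == s).sum(axis=0) for s in _STATES], axis=-1).astype(float)


def _dm_from_counts(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log marginal from state counts.

    counts has shape (..., experiments, 3); returns shape (...).
    """
    a_sum = alpha.sum()
    n = counts.sum(axis=-1)
    per_col = (
        gammaln(a_sum)
        - gammaln(a_sum + n)
        + (gammaln(alpha + counts) - gammaln(alpha)).sum(axis=-1)
    )
    return per_col.sum(axis=-1)


def dm_log_marginal(rows, alpha=(1.0, 1.0, 1.0)) -> float:
    """Log marginal likelihood of a trinary submatrix under one cluster.

    Columns (experiments) are independent; within a column the state counts
    follow a Dirichlet-multinomial with pseudocounts ``alpha``.  An empty
    submatrix has probability one (log 0.0).
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (3,) or (alpha <= 0).any():
        raise ValueError("alpha must be three positive pseudocounts")
    rows = np.asarray(rows)
    if rows.size == 0:
        return 0.0
    return float(_dm_from_counts(_state_counts(rows), alpha))


def _merge_candidate(
    left: BhcNode, right: BhcNode, alpha: np.ndarray, log_conc: float
) -> BhcNode:
    """Evaluate the hypothetical merge of two subtrees."""
    counts = left.counts + right.counts
    n_k = left.size + right.size
    log_h1 = float(_dm_from_counts(counts, alpha))
    log_dp = log_conc + gammaln(n_k)          # conc * Gamma(n_k)
    log_dd = left.log_d + right.log_d
    log_d = np.logaddexp(log_dp, log_dd)
    log_pi = log_dp - log_d
    log_1m_pi = log_dd - log_d
    log_tree = np.logaddexp(
        log_pi + log_h1, log_1m_pi + left.log_tree + right.log_tree
    )
    r = float(np.exp(log_pi + log_h1 - log_tree))
    return BhcNode(
        members=tuple(sorted(left.members + right.members)),
        children=None,  # filled in when the merge is committed
        counts=counts,
        log_h1=log_h1,
        log_tree=float(log_tree),
        log_d=float(log_d),
        log_pi=float(log_pi),
        r=min(r, 1.0),
    )


def build(data, cfg: BhcConfig | None = None) -> BhcTree:
    """Greedy Bayesian hierarchical clustering of a trinary matrix.

    ``data`` is items x experiments over {-1, 0, +1} (a DataFrame's values
    or any array-like).  Ties on the merge posterior are broken towards the
    candidate pair with the lexicographically smallest (min id, max id), so
    the construction is fully deterministic.
    """
    cfg = cfg or BhcConfig()
    matrix = np.asarray(getattr(data, "states", data))
    matrix = np.asarray(getattr(matrix, "values", matrix))
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("data must be a non-empty items x experiments matrix")
    n = matrix.shape[0]
    alpha = np.asarray(cfg.alpha, dtype=float)
    log_conc = float(np.log(cfg.conc))

    nodes: list[BhcNode] = []
    for i in range(n):
        counts = _state_counts(matrix[i])
        log_h1 = float(_dm_from_counts(counts, alpha))
        nodes.append(
            BhcNode(
                members=(i,),
                children=None,
                counts=counts,
                log_h1=log_h1,
                log_tree=log_h1,
                log_d=log_conc,
                log_pi=0.0,
                r=1.0,
            )
        )
    if n == 1:
        return BhcTree(nodes=nodes, n_items=1, config=cfg)

    active = list(range(n))
    candidates: dict[tuple[int, int], BhcNode] = {}
    for ai in range(n):
        for aj in range(ai + 1, n):
            candidates[(ai, aj)] = _merge_candidate(nodes[ai], nodes[aj], alpha, log_conc)

    while len(active) > 1:
        best_pair = max(candidates, key=lambda p: (candidates[p].r, (-p[0], -p[1])))
        merged = candidates.pop(best_pair)
        merged.children = best_pair
        new_id = len(nodes)
        nodes.append(merged)
        i, j = best_pair
        active = [a for a in active if a not in (i, j)]
        for pair in [p for p in candidates if i in p or j in p]:
            del candidates[pair]
        for a in active:
            candidates[(a, new_id)] = _merge_candidate(nodes[a], merged, alpha, log_conc)
        active.append(new_id)

    return BhcTree(nodes=nodes, n_items=n, config=cfg)


def cut(tree: BhcTree, threshold: float | None = None) -> Partition:
    """Flatten the tree into clusters by the merge-posterior criterion.

    Descending from the root, a node whose merge posterior r is at least the
    threshold becomes one flat cluster; otherwise its children are visited.
    Leaves always form clusters (r = 1 by convention).  Cluster indices are
    contiguous from 0 in order of each cluster's smallest item.
    """
    threshold = tree.config.cut_threshold if threshold is None else threshold
    blocks: list[tuple[int, ...]] = []

    def descend(idx: int) -> None:
        node = tree.nodes[idx]
        if node.children is None or node.r >= threshold:
            blocks.append(node.members)
        else:
            descend(node.children[0])
            descend(node.children[1])

    descend(len(tree.nodes) - 1)
    blocks.sort(key=min)
    labels = np.empty(tree.n_items, dtype=int)
    for ci, block in enumerate(blocks):
        labels[list(block)] = ci
    return Partition(labels=labels, n_clusters=len(blocks))


def cut_map(tree: BhcTree) -> Partition:
    """Tree-consistent MAP flat partition under the cluster prior.

    Dynamic programming over the merge tree: each node either becomes one
    flat cluster (conc * Gamma(n) prior mass times its Dirichlet-multinomial
    marginal) or defers to the best partitions of its children, whichever
    scores higher.  This maximizes the same joint prior x likelihood that
    :func:`partition_log_score` evaluates, restricted to clusters the greedy
    agglomeration formed, and so measures how much the greedy tree loses
    against free enumeration.  The threshold rule of :func:`cut` is cheaper
    and is what the bootstrap pipeline uses; ``cut_map`` answers "what is
    the best number of clusters" for a single dataset.
    """
    log_conc = float(np.log(tree.config.conc))

    def best(idx: int) -> tuple[float, list[tuple[int, ...]]]:
        node = tree.nodes[idx]
        own = (log_conc + float(gammaln(node.size)) + node.log_h1, [node.members])
        if node.children is None:
            return own
        ls, lb = best(node.children[0])
        rs, rb = best(node.children[1])
        if ls + rs > own[0]:
            return ls + rs, lb + rb
        return own

    _, blocks = best(len(tree.nodes) - 1)
    blocks.sort(key=min)
    labels = np.empty(tree.n_items, dtype=int)
    for ci, block in enumerate(blocks):
        labels[list(block)] = ci
    return Partition(labels=labels, n_clusters=len(blocks))


def partition_log_score(data, labels, cfg: BhcConfig | None = None) -> float:
    """Joint log prior x likelihood of a flat partition.

    Scores a partition under the same model the tree construction uses:
    each block contributes conc * Gamma(n_block) of prior mass and a
    Dirichlet-multinomial marginal likelihood.  Used to compare the greedy
    tree cut against exhaustive enumeration of set partitions.
    """
    cfg = cfg or BhcConfig()
    matrix = np.asarray(getattr(data, "values", data))
    labels = np.asarray(labels)
    alpha = np.asarray(cfg.alpha, dtype=float)
    score = 0.0
    for lab in np.unique(labels):
        block = matrix[labels == lab]
        score += (
            np.log(cfg.conc)
            + gammaln(len(block))
            + dm_log_marginal(block, alpha)
        )
    return float(score)
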