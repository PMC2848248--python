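"""Consensus of bootstrap clusterings: co-assignment counts and Ward tree.

Each bootstrap replicate of the discretized expression data is clustered
independently; for every pair of items the number of replicates in which
they land in the same cluster is counted.  Those co-clustering similarities,
turned into distances d = 1 - s/B, feed an agglomerative Ward clustering
whose dendrogram is the final consensus structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from . import bhc as _bhc
from . import expression_boot as _eb

__all__ = [
    "ConsensusMatrix",
    "Dendrogram",
    "PipelineResult",
    "coclustering",
    "ward_tree",
    "run_pipeline",
]


@dataclass
class ConsensusMatrix:
    """Symmetric items x items co-assignment counts over B replicates."""

    counts: np.ndarray
    n_replicates: int
    labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.array_equal(c, c.T):
            raise ValueError("co-clustering counts must be symmetric")
        if not (np.diag(c) == self.n_replicates).all():
            raise ValueError("diagonal must equal the replicate count")
        if c.min() < 0 or c.max() > self.n_replicates:
            raise ValueError("counts must lie in [0, B]")

    def distances(self) -> np.ndarray:
        """Dissimilarity d = 1 - counts/B, in [0, 1], zero iff always together."""
        return 1.0 - self.counts / self.n_replicates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Ward merge history in scipy linkage form plus leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (contiguous from 0) at a requested cluster count."""
        flat = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        _, labels = np.unique(flat, return_inverse=True)
        return labels

    def to_newick(self) -> str:
        node = to_tree(self.linkage)

        def render(nd) -> str:
            if nd.is_leaf():
                return self.labels[nd.id]
            length_l = nd.dist - nd.left.dist
            length_r = nd.dist - nd.right.dist
            return f"({render(nd.left)}:{length_l:.6g},{render(nd.right)}:{length_r:.6g})"

        return render(node) + ";"


def coclustering(partitions) -> ConsensusMatrix:
    """Count, for each item pair, the replicates assigning them together.

    ``partitions`` is a sequence of :class:`srokit.bhc.Partition` (or plain
    label arrays), all over the same items in the same order.
    """
    label_rows = [np.asarray(getattr(p, "labels", p)) for p in partitions]
    if not label_rows:
        raise ValueError("at least one partition is required")
    n = len(label_rows[0])
    if any(len(row) != n for row in label_rows):
        raise ValueError("all partitions must cover the same item set")
    counts = np.zeros((n, n), dtype=int)
    for row in label_rows:
        counts += row[:, None] == row[None, :]
    return ConsensusMatrix(
        counts=counts, n_replicates=len(label_rows), labels=[str(i) for i in range(n)]
    )


def ward_tree(sim: ConsensusMatrix, labels: list[str] | None = None) -> Dendrogram:
    """Ward agglomeration of the consensus distances.

    The Lance-Williams Ward update is applied directly to the distance
    matrix d = 1 - counts/B (the co-clustering distances are not Euclidean
    embeddings; this is the usual consensus-heatmap practice and is treated
    as an approximation).
    """
    labels = labels or sim.labels
    dist = sim.distances()
    if len(labels) == 1:
        return Dendrogram(linkage=np.empty((0, 4)), labels=labels)
    condensed = squareform(dist, checks=False)
    return Dendrogram(linkage=linkage(condensed, method="ward"), labels=labels)


@dataclass
class PipelineResult:
    profile: _eb.DEProfile
    partitions: list[_bhc.Partition]
    consensus: ConsensusMatrix
    dendrogram: Dendrogram


def run_pipeline(
    experiments: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    n_bootstrap: int = 1000,
    seed: int = 0,
    variance_mode: str = "raw",
    bhc_config: _bhc.BhcConfig | None = None,
    cluster_experiments: bool = False,
) -> PipelineResult:
    """End-to-end consensus clustering of expression experiments.

    summarize -> parametric bootstrap (B draws) -> discretize each draw ->
    Bayesian hierarchical clustering and posterior cut per draw ->
    co-clustering counts -> Ward dendrogram.  All randomness flows from
    ``seed``.  With ``cluster_experiments`` the discretized matrices are
    transposed so experiments, not genes, are the clustered items.
    """
    bhc_config = bhc_config or _bhc.BhcConfig()
    profile = _eb.summarize_experiments(experiments, variance_mode=variance_mode)
    draws = _eb.bootstrap(profile, n_bootstrap, seed)
    partitions = []
    for b in range(n_bootstrap):
        states = _eb.discretize(draws[b])
        if cluster_experiments:
            states = states.T
        tree = _bhc.build(states, bhc_config)
        partitions.append(_bhc.cut(tree))
    consensus = coclustering(partitions)
    item_labels = (
        profile.experiment_ids if cluster_experiments else profile.gene_ids
    )
    consensus.labels = [str(l) for l in item_labels]
    dendro = ward_tree(consensus)
    return PipelineResult(
        profile=profile,
        partitions=partitions,
        consensus=consensus,
        dendrogram=dendro,
    )
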