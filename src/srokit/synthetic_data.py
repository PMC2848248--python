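"""Synthetic inputs with planted ground truth.

Two generators make every downstream stage testable without external
downloads:

* :func:`simulate_expression` emulates the structure of public stress
  microarray series: per-experiment treatment/control replicate sets on the
  log2 scale with Gaussian noise and planted up/none/down response patterns
  shared within gene clusters.
* :func:`simulate_protein_family` writes protein records that embed the
  packaged domain mini-profile consensus blocks (WWE, PARP core, RST) at
  recorded positions, with chosen catalytic-triad residues and beta4-beta5
  loop length planted inside the PARP-core scaffold.

:func:`build_landmark_query` additionally constructs single sequences whose
triad landmarks sit at requested full-protein coordinates, for exercising the
alignment-based triad extraction against published coordinate geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._refdata import fold_reference_raw, miniprofile_raw

__all__ = [
    "ExpressionTruth",
    "ProteinTruth",
    "ArchitectureTemplate",
    "simulate_expression",
    "simulate_protein_family",
    "build_landmark_query",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ExpressionTruth:
    """Planted structure of a simulated expression compendium."""

    gene_ids: list[str]
    cluster_labels: np.ndarray
    pattern: np.ndarray          # clusters x experiments, entries in {-delta, 0, +delta}
    delta: float
    noise_sd: float
    n_reps: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "cluster_labels": self.cluster_labels.tolist(),
            "pattern": self.pattern.tolist(),
            "delta": self.delta,
            "noise_sd": self.noise_sd,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


@dataclass
class ProteinTruth:
    """Planted domain spans and active-site features of simulated proteins."""

    records: list[tuple[str, str]]
    planted_domains: dict[str, list[tuple[str, int, int]]]  # 1-based inclusive
    planted_triad: dict[str, tuple[str, int, str, int, str, int]]
    planted_loop_len: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "records": [{"id": rid, "length": len(seq)} for rid, seq in self.records],
            "planted_domains": self.planted_domains,
            "planted_triad": self.planted_triad,
            "planted_loop_len": self.planted_loop_len,
        }


def simulate_expression(
    n_clusters: int,
    genes_per_cluster: int,
    experiments: int,
    delta: float = 2.0,
    noise_sd: float = 0.3,
    n_reps: int = 3,
    seed: int = 0,
    pattern: np.ndarray | None = None,
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], ExpressionTruth]:
    """Simulate treatment/control replicate matrices with planted clusters.

    Each cluster carries one response pattern over experiments with entries
    in {-delta, 0, +delta} (log2 units); by default cluster patterns are
    drawn uniformly and resampled until every pair differs in more than half
    of the experiments.  That bound comes from the clustering model itself:
    under the Dirichlet-multinomial likelihood with the Gamma(n)
    cluster-size prior, merging two equal-size clusters scores higher than
    keeping them apart whenever their discretized patterns agree in half or
    more of the columns, so a planted partition closer than that is not
    recoverable even in principle.  Pass ``pattern``
    (clusters x experiments, entries in {-1, 0, +1}, scaled by delta) to
    plant a specific design, e.g. fully opposing responses.  Per-gene
    baselines are drawn once from Gaussian(8, 1) on the log2 scale (a
    typical normalized-intensity range); replicate values add Gaussian noise
    of standard deviation ``noise_sd``.

    Returns a mapping experiment id -> (treatment, control) genes x
    replicates DataFrames, plus the ground truth.
    """
    if min(n_clusters, genes_per_cluster, experiments, n_reps) < 1:
        raise ValueError("all counts must be >= 1")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for downstream variance estimates")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    levels = np.array([-delta, 0.0, delta])
    if pattern is not None:
        pattern = np.asarray(pattern, dtype=float) * delta
        if pattern.shape != (n_clusters, experiments):
            raise ValueError("pattern must be clusters x experiments")
        if not np.isin(pattern, levels).all():
            raise ValueError("pattern entries must lie in {-1, 0, +1}")
    else:
        min_hamming = min(experiments, experiments // 2 + 1)
        for _ in range(1000):
            pattern = levels[rng.integers(0, 3, size=(n_clusters, experiments))]
            diffs = (pattern[:, None, :] != pattern[None, :, :]).sum(axis=2)
            np.fill_diagonal(diffs, experiments)
            if n_clusters == 1 or diffs.min() >= min_hamming:
                break
        else:
            raise RuntimeError(
                "could not draw sufficiently distinct cluster patterns; "
                "reduce n_clusters or increase experiments"
            )

    n_genes = n_clusters * genes_per_cluster
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    labels = np.repeat(np.arange(n_clusters), genes_per_cluster)
    baseline = rng.normal(8.0, 1.0, size=n_genes)

    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for e in range(experiments):
        exp_id = f"exp{e + 1}"
        shift = baseline + pattern[labels, e]
        treat = rng.normal(shift[:, None], noise_sd, size=(n_genes, n_reps))
        ctrl = rng.normal(baseline[:, None], noise_sd, size=(n_genes, n_reps))
        out[exp_id] = (
            pd.DataFrame(
                treat, index=gene_ids,
                columns=[f"{exp_id}_treatment_{r + 1}" for r in range(n_reps)],
            ),
            pd.DataFrame(
                ctrl, index=gene_ids,
                columns=[f"{exp_id}_control_{r + 1}" for r in range(n_reps)],
            ),
        )
    truth = ExpressionTruth(
        gene_ids=gene_ids,
        cluster_labels=labels,
        pattern=pattern,
        delta=delta,
        noise_sd=noise_sd,
        n_reps=n_reps,
        seed=seed,
    )
    return out, truth


@dataclass
class ArchitectureTemplate:
    """Which domains to embed in one simulated protein, N to C order.

    ``triad`` and ``loop_len`` shape the embedded PARP-core scaffold; they
    default to the reference's own H/Y/E and 37-residue beta4-beta5 loop.
    """

    domains: tuple[str, ...] = ("WWE", "PARP_core", "RST")
    triad: tuple[str, str, str] | None = None
    loop_len: int | None = None
    record_id: str | None = None


def _resize(native: str, n: int, rng) -> str:
    """Shrink or grow a linker segment from its middle.

    Keeping the native flanks intact anchors the pairwise alignment on both
    sides, so length changes are absorbed as indels inside the linker rather
    than at the adjacent fold landmarks.
    """
    if n < 0:
        raise ValueError("segment length must be >= 0")
    if n <= len(native):
        head = (n + 1) // 2
        return native[:head] + native[len(native) - (n - head):]
    mid = len(native) // 2
    insert = "".join(_AA[i] for i in rng.integers(0, 20, n - len(native)))
    return native[:mid] + insert + native[mid:]


def _modified_core(triad, loop_len, rng) -> tuple[str, tuple[int, int, int], int]:
    """Reference PARP core with requested triad residues and loop length.

    Returns (sequence, triad core positions, loop length), 1-based positions
    within the returned block.
    """
    ref = fold_reference_raw()
    core = list(ref["sequence"])
    spans = ref["spans"]
    l1 = spans["beta1"][1]
    b2 = spans["beta2"]
    l2 = b2[0] + int(np.ceil((b2[1] - b2[0] + 1) / 2)) - 1
    b4_end = spans["beta4"][1]
    b5_start = spans["beta5"][0]
    native_loop = b5_start - b4_end - 1

    r1, r2, r3 = triad if triad is not None else (core[l1 - 1], core[l2 - 1], core[b5_start - 1])
    for r in (r1, r2, r3):
        if r not in _AA:
            raise ValueError(f"triad residue {r!r} is not a standard amino acid")
    loop_len = native_loop if loop_len is None else int(loop_len)
    if loop_len < 0:
        raise ValueError("loop length must be >= 0")

    core[l1 - 1], core[l2 - 1] = r1, r2
    head = core[: b4_end]                       # through beta4
    tail = core[b5_start - 1:]                  # beta5 onward
    tail[0] = r3
    native_linker = "".join(core[b4_end : b5_start - 1])
    loop = _resize(native_linker, loop_len, rng)
    seq = "".join(head) + loop + "".join(tail)
    l3 = b4_end + loop_len + 1
    return seq, (l1, l2, l3), loop_len


def simulate_protein_family(
    arch_spec: list[ArchitectureTemplate | dict],
    background_len: int = 40,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], ProteinTruth]:
    """Build protein records embedding the packaged domain consensus blocks.

    Inter-domain background is uniform-random amino acids, so consensus
    blocks score at the profile maximum and detection is deterministic.
    Planted PARP-core domain spans refer to the loop-invariant profile window
    of the scaffold (the region the scanner is expected to report).
    """
    raw = miniprofile_raw()
    profiles = raw["profiles"]
    parp_off = raw["parp_core_offset"]
    parp_len = len(profiles["PARP_core"])
    rng = np.random.default_rng(seed)

    records: list[tuple[str, str]] = []
    planted_domains: dict[str, list[tuple[str, int, int]]] = {}
    planted_triad: dict[str, tuple] = {}
    planted_loop: dict[str, int] = {}

    for k, template in enumerate(arch_spec):
        if isinstance(template, dict):
            template = ArchitectureTemplate(**template)
        rid = template.record_id or f"syn{k + 1:03d}"
        for name in template.domains:
            if name not in ("WWE", "PARP_core", "RST"):
                raise ValueError(f"unknown domain name {name!r}")
        seq_parts = ["".join(_AA[i] for i in rng.integers(0, 20, background_len))]
        pos = background_len
        domains_here: list[tuple[str, int, int]] = []
        for name in template.domains:
            if name == "PARP_core":
                block, (l1, l2, l3), loop_len = _modified_core(
                    template.triad, template.loop_len, rng
                )
                domains_here.append(
                    ("PARP_core", pos + parp_off + 1, pos + parp_off + parp_len)
                )
                planted_triad[rid] = (
                    block[l1 - 1], pos + l1,
                    block[l2 - 1], pos + l2,
                    block[l3 - 1], pos + l3,
                )
                planted_loop[rid] = loop_len
            else:
                block = profiles[name]
                domains_here.append((name, pos + 1, pos + len(block)))
            seq_parts.append(block)
            pos += len(block)
            linker = "".join(_AA[i] for i in rng.integers(0, 20, background_len))
            seq_parts.append(linker)
            pos += background_len
        seq = "".join(seq_parts)
        records.append((rid, seq))
        planted_domains[rid] = domains_here

    truth = ProteinTruth(
        records=records,
        planted_domains=planted_domains,
        planted_triad=planted_triad,
        planted_loop_len=planted_loop,
    )
    return records, truth


def build_landmark_query(
    triad: tuple[str, str, str],
    positions: tuple[int, int, int],
    loop_len: int,
    seed: int = 0,
    c_term_pad: int = 25,
) -> str:
    """Construct a protein whose triad landmarks sit at given coordinates.

    The query keeps the packaged scaffold's fold blocks intact (so the
    anchoring alignment can place them) while re-sizing the inter-fold
    linkers and the beta4-beta5 loop so that the three landmark residues
    land at the requested 1-based full-protein positions.  This mirrors the
    coordinate geometry of published catalytic cores (e.g. a reference-like
    H/Y/E at 862/896/988 with loop 37, or a degenerate L/H/N at 333/365/428
    with loop 5) without using any real sequence.
    """
    ref = fold_reference_raw()
    core = ref["sequence"]
    spans = ref["spans"]
    p1, p2, p3 = positions
    if not p1 < p2 < p3:
        raise ValueError("landmark positions must increase")
    r1, r2, r3 = triad
    for r in (r1, r2, r3):
        if r not in _AA:
            raise ValueError(f"triad residue {r!r} is not a standard amino acid")
    rng = np.random.default_rng(seed)

    l1 = spans["beta1"][1]
    b2s, b2e = spans["beta2"]
    l2 = b2s + int(np.ceil((b2e - b2s + 1) / 2)) - 1
    b4s, b4e = spans["beta4"]
    b5s = spans["beta5"][0]

    n_pad = p1 - l1
    if n_pad < 0:
        raise ValueError(f"first landmark position must be >= {l1}")
    linker1 = (p2 - p1) - (l2 - l1) + (b2s - l1 - 1)
    if linker1 < 0:
        raise ValueError("landmark spacing p2 - p1 too small for the fold blocks")

    # Fixed blocks between landmark 2 and the beta5 start: beta2 tail,
    # alpha2, beta3, beta4 plus three native linkers that absorb the slack.
    seg = {
        "link_a": (b2e + 1, spans["alpha2"][0] - 1),
        "alpha2": spans["alpha2"],
        "link_b": (spans["alpha2"][1] + 1, spans["beta3"][0] - 1),
        "beta3": spans["beta3"],
        "link_c": (spans["beta3"][1] + 1, b4s - 1),
        "beta4": (b4s, b4e),
    }
    fixed = (b2e - l2) + sum(
        seg[name][1] - seg[name][0] + 1 for name in ("alpha2", "beta3", "beta4")
    )
    native_links = {n: seg[n][1] - seg[n][0] + 1 for n in ("link_a", "link_b", "link_c")}
    slack = (p3 - p2) - fixed - loop_len - 1 - sum(native_links.values())
    links = dict(native_links)
    if slack >= 0:
        links["link_c"] += slack
    else:
        for name in ("link_c", "link_b", "link_a"):
            take = min(links[name], -slack)
            links[name] -= take
            slack += take
        if slack < 0:
            raise ValueError("landmark spacing p3 - p2 too small for the fold blocks")

    def rand(n: int) -> str:
        return "".join(_AA[i] for i in rng.integers(0, 20, n))

    def coreseg(a: int, b: int) -> str:
        return core[a - 1 : b]

    # linkers are the native reference segments resized from their middles,
    # so alignment indels fall inside them, not on the flanking landmarks
    parts = [
        rand(n_pad),
        coreseg(1, l1 - 1), r1,                    # through landmark 1
        _resize(coreseg(l1 + 1, b2s - 1), linker1, rng),
        coreseg(b2s, l2 - 1), r2, coreseg(l2 + 1, b2e),
        _resize(coreseg(*seg["link_a"]), links["link_a"], rng), coreseg(*seg["alpha2"]),
        _resize(coreseg(*seg["link_b"]), links["link_b"], rng), coreseg(*seg["beta3"]),
        _resize(coreseg(*seg["link_c"]), links["link_c"], rng), coreseg(*seg["beta4"]),
        _resize(coreseg(b4e + 1, b5s - 1), loop_len, rng),
        r3, coreseg(b5s + 1, len(core)),
        rand(c_term_pad),
    ]
    seq = "".join(parts)
    for pos, res in zip(positions, triad):
        assert seq[pos - 1] == res, "internal landmark placement error"
    return seq
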