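# srokit

Analysis toolkit for the plant SRO protein family (SIMILAR-TO-RCD-ONE):
bootstrapped Bayesian consensus clustering of stress expression profiles,
and structural classification of SRO/PARP proteins — domain architecture
typing, catalytic-triad extraction, activity prediction, neighbour-joining
phylogeny and family nomenclature.

SROs carry the catalytic core of the poly(ADP-ribose) polymerase (PARP)
domain and a C-terminal RST domain, with an N-terminal WWE domain present in
one structural type.  Two questions drive the analyses here: how the family
members respond transcriptionally across stress treatments, and whether
their PARP-like cores can still act as ADP-ribosyl transferases.  The
package is aimed at comparative genomicists and protein-family curators who
want those analyses reproducible end to end on their own (or simulated)
inputs.

## Expression track

Per experiment *e* and gene *g*, treatment and control replicate arms (log2
scale) are combined into a differential expression
`DE = mean(treatment) − mean(control)` with variance estimate
`σ² = s²_t + s²_c` (sum of the arms' log-expression sample variances; a
`variance_mode="of_mean"` alternative scales each by its replicate count).
A parametric bootstrap draws `B` samples per (g, e) from `N(DE, σ²)`; each
draw is discretized to down / none / up at log2 thresholds −1 and +1
(boundaries map to "none").  Every bootstrap replicate is clustered by
Bayesian agglomerative hierarchical clustering: cluster columns follow a
Dirichlet-multinomial over the three states (pseudocounts α = (1,1,1)),
subtrees get Dirichlet-process-style prior mass
`π_k = conc·Γ(n_k)/d_k`, `d_k = conc·Γ(n_k) + d_l·d_r`, and the pair with
the highest merge posterior

    r_k = π_k p(D_k|H1) / [π_k p(D_k|H1) + (1−π_k) p(D_l|T_l) p(D_r|T_r)]

is joined at each step; the flat partition cuts the tree where `r_k` drops
below 0.5 (a tree-consistent MAP cut, `bhc.cut_map`, is also provided).
Pairwise co-clustering counts across the `B` partitions, converted to
distances `d = 1 − s/B`, feed a Ward dendrogram — the consensus structure.

## Protein track

Domain architectures are typed by scanning packaged position-weight-matrix
mini-profiles (WWE, PARP core, RST): type A = WWE+PARP+RST in N→C order,
type B = PARP+RST without WWE, otherwise incomplete.  For activity, a query
is anchored to a fold-annotated PARP-core reference by global alignment
(BLOSUM62, affine gaps, free end gaps); the catalytic triad is read off
three fold landmarks (C-terminus of β1, middle of β2, N-terminus of β5) and
the β4–β5 loop length is counted between the strand landmarks.  The rule
cascade then predicts: catalytic E + long loop → PARP; NAD-contacting H+Y →
mART; Y retained + experimental NAD binding → mART (substrate-assisted);
otherwise inactive.  Neighbour joining (Saitou–Nei, exact on additive
matrices) with outgroup rooting assigns phylogenetic groups I/II, and the
nomenclature operation produces names like `PtSRO1c`.

## Worked example

```sh
python examples/01_expression_consensus.py
```

```
planted clusters: [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
recovered (Ward cut at 3): [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
adjusted Rand index vs truth: 1.000
co-clustering counts within the first planted cluster (B=200):
[[200 200 200 200]
 [200 200 200 200]
 [200 200 200 200]
 [200 200 200 200]]
```

Twelve genes in three planted response clusters (effect ±2 log2 units,
noise SD 0.3, three replicates per arm) are recovered exactly: an adjusted
Rand index of 1.0 means the consensus partition equals the planted one, and
the 200/200 co-clustering counts show the first cluster's genes were never
separated in any bootstrap replicate.  The other examples cover domain
typing (`02`), activity prediction — including the 16/16 concordance with
the curated active-site table (`03`), phylogeny and grouping (`04`) and
nomenclature (`05`).

A thin CLI wraps the same pipelines:

```sh
srokit simulate --preset demo --out demo/
srokit cluster --expression demo/expression.tsv --bootstrap 200 --out demo_out/
srokit triad --fasta demo/proteins.faa --out calls.tsv
```

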