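# Methods

This note documents the models, parameter choices and numerical decisions
behind srokit, and what the synthetic benchmarks do and do not demonstrate.

## Differential expression and the parametric bootstrap

Inputs are log2-scale replicate matrices (RMA-like intensities); no log
transform is applied.  For each gene and experiment,
`DE = mean(treatment) − mean(control)`.  Two variance estimates are
offered because "sum of the treatment and control variances" is ambiguous
about replicate-number scaling:

* `raw` (default): `s²_t + s²_c`, the plain sum of sample variances;
* `of_mean`: `s²_t/n_t + s²_c/n_c`, the variance of the DE estimator.

`raw` is deliberately conservative (wider bootstrap spread); the chosen
mode is recorded in run metadata.  A single-replicate arm is an error
unless explicitly overridden (then it contributes zero variance).

The parametric bootstrap draws `B` samples per (gene, experiment) from
`N(DE, σ²)`, `B = 1000` by default (tests and benchmarks use 200 to keep
runtimes in seconds; the acceptance script states the sizes it used).
Replicate streams are spawned from one seed via `numpy.random.SeedSequence`,
so replicate *b* is reproducible in isolation and a shorter run is a prefix
of a longer one.

Discretization maps log2 DE to down/none/up at thresholds −1 and +1.  The
middle band is closed: values exactly ±1 are "no regulation".  (The
inequality as usually transcribed, "−1 ≥ DE ≤ 1", is an obvious typo for
−1 ≤ DE ≤ 1.)  NaN input is rejected rather than silently banded.

## Bayesian hierarchical clustering

Each bootstrap replicate's trinary matrix is clustered by greedy Bayesian
agglomeration.  Within a cluster, experiments are conditionally independent
and each experiment's state counts follow a Dirichlet-multinomial with
symmetric pseudocounts α = (1,1,1) — the uniform choice, since nothing in
the source analysis pins the likelihood family or hyperparameters; the
concentration of the cluster-size prior is `conc = 1`.  All evidence
arithmetic is in log space; the tree evidence mixture uses log-sum-exp, and
`log(1−π_k)` is computed exactly as `log d_l + log d_r − log d_k`.  Ties in
the merge posterior break toward the lexicographically smallest (min id,
max id) candidate pair, making construction deterministic; item order can
therefore matter only through exact ties.

Two flat-partition extractions are provided:

* `cut(tree, threshold)`: descend from the root, a node with `r ≥ 0.5`
  becomes one cluster.  This is the rule the bootstrap pipeline uses per
  replicate — cheap, and differences wash out in the consensus.
* `cut_map(tree)`: dynamic programming for the tree-consistent partition
  maximizing the flat score `Σ_blocks [ln conc + lnΓ(n_b) + ln DM(block)]`.
  The threshold rule compares "merge" against the *mixture* of all subtree
  partitions, which systematically under-merges relative to the flat MAP;
  on random 4×4 matrices its partition ranks in the top two of exhaustive
  enumeration only ~80% of the time, while `cut_map` reaches ~100% —
  i.e. the greedy tree itself loses almost nothing.  `cut_map` is therefore
  the answer to "what is the best number of clusters" for a single dataset.

## Consensus and Ward linkage

Co-clustering counts `s_ij` (number of replicates assigning *i* and *j*
together) become distances `d_ij = 1 − s_ij/B`, bounded in [0,1] and zero
iff always co-clustered.  Ward linkage is applied directly to this distance
matrix via the Lance–Williams update (scipy).  These distances are not a
Euclidean embedding, so "Ward" is the common consensus-heatmap
approximation, not a variance decomposition; dendrogram heights are
monotone by construction and only their order is interpreted.

## What the expression generator emulates — and the identifiability bound

`simulate_expression` plants per-cluster response patterns over experiments
with entries in {−δ, 0, +δ}, per-gene baselines from N(8, 1) on the log2
scale (a typical normalized-intensity range; the baseline cancels in DE),
and i.i.d. Gaussian replicate noise.  It does not simulate probe-level
effects, normalization artifacts, batch structure, or correlated noise —
recovery results bound what the pipeline can do under its own model
assumptions, not microarray reality.

Random patterns are resampled until every cluster pair differs in more than
half of the experiments.  This bound follows from the clustering model
itself, not from tuning: for two equal clusters of size *m* whose
discretized patterns agree in a column, merging gains
`ln[DM(2m·same)/DM(m·same)²]` (+1.61 nats at m = 4), while a differing
column costs 2.64 nats, and the size prior contributes
`lnΓ(2m) − 2lnΓ(m)` (+4.94 nats at m = 4) in favour of merging.  At 8
experiments the merged hypothesis therefore outscores the planted split
whenever patterns differ in ≤ 4 columns — even exhaustive enumeration
prefers the merge, so such a truth is unrecoverable *in principle*.  A
recovery benchmark must plant a recoverable truth; hence the > e/2
separation rule.  An explicit `pattern` argument lets callers plant any
design, including deliberately unrecoverable ones.

## Domain mini-profiles

The WWE, PARP-core and RST detectors are ungapped position weight matrices
built from packaged consensus strings (match weight 0.7, remainder uniform;
log-odds against a uniform background; threshold 0.8 × maximum score;
greedy best-score-first non-overlapping placement).  The consensus strings
are synthetic — fixed-RNG sequences standing in for the real PROSITE/Pfam
signatures, which cannot be redistributed here — so detection is exact for
sequences that embed the packaged blocks (the generator guarantees this)
and the scanner's span/order/threshold logic is what is actually under
test.  The PARP-core profile covers only the β1–β3 region of the scaffold,
which is invariant to β4–β5 loop changes; it tolerates ~14% mismatches, so
triad substitutions never mask detection.  No E-values, no gapped matches:
scanning real proteins would require the real profiles.

## Triad extraction and activity rules

The fold reference is a synthetic 230-residue PARP-core scaffold whose
annotation geometry mirrors the published human PARP1 core: strands β1–β6
and helix α2, triad landmarks at the β1 C-terminus (H), β2 middle (Y,
"middle" fixed as the ⌈len/2⌉-th span residue) and β5 N-terminus (E), a
37-residue β4–β5 loop, and a coordinate offset of 787 so landmark
full-protein positions are 862/896/988.  Queries are anchored by biopython
global alignment (BLOSUM62, gap open −11 / extend −1, free end gaps so the
core may sit anywhere); every reference column maps to a query position or
a gap.  A gapped landmark yields residue '−', a warning, and a forced
"inactive" call; a gapped loop endpoint falls back to the nearest aligned
position inside the strand.

Activity cascade: (1) third-landmark E with loop ≥ `long_loop_min` → PARP;
(2) H and Y at landmarks 1–2 → mART; (3) Y at landmark 2 plus positive
experimental NAD-binding evidence → mART (substrate-assisted mechanism);
(4) otherwise inactive.  `long_loop_min = 30`: observed loop lengths are
bimodal (5–6 vs 36–38), so any cutoff between the bands classifies
identically (property-tested); 30 is exposed in config.  Rule 3 demands
*positive* evidence — "ND" is not enough — which is exactly what separates
the substrate-assisted mART from Y-retaining inactive proteins.  Rule 1
fires on degenerate first/second landmarks too (e.g. C/V/E with a long
loop), matching the literature classification of such PARPs.

Coordinate-exact benchmarks use `build_landmark_query`: synthetic sequences
whose fold blocks are the reference's own, with linkers and loop resized
from their middles so that the triad lands at requested full-protein
coordinates (e.g. the degenerate L/H/N at 333/365/428 with loop 5).
Keeping native linker flanks anchors indels mid-linker, away from
landmarks.  These stand-ins validate the coordinate arithmetic of
extraction; they do not test alignment robustness against real sequence
divergence, where hand adjustment guided by fold predictions is the
practice the automation replaces.

## Phylogeny

p-distances use pairwise gap deletion (columns where either sequence has a
gap are skipped for that pair); an optional Poisson correction
`−ln(1−p)` is available.  Neighbour joining is the classic Saitou–Nei
algorithm: Q-matrix selection (ties to the lowest index pair), standard
branch-length estimates with negative values clamped to zero and the
deficit moved to the sibling (sum preserved), termination at a central
trifurcation.  It recovers additive metrics exactly (patristic error
~1e−15 in the benchmarks) and is cross-checked against an independent NJ
implementation on non-additive input.  Outgroup rooting splits the edge
above the outgroup's MRCA at its midpoint; a non-monophyletic outgroup
warns and roots at the MRCA edge regardless.  Group I/II labels propagate
from the smallest enclosing clade containing references of a single group;
mixed or reference-free clades leave a leaf "unassigned".  Finer subgroup
structure (Ia/Ib/Ic, IIa/IIb) is read by experts off tree shape and is not
automated.

## Problem sizes and runtime

Benchmarks are sized for seconds-scale runs on one CPU: recovery uses 12
genes × 8 experiments × B = 200 over 20 seeds; enumeration comparisons use
4-item datasets (15 partitions); marginal-likelihood normalization is
verified exhaustively up to 3 items × 2 experiments (≤ 729 datasets per
shape); NJ exactness uses 10-leaf trees.  The bootstrap default B = 1000 is
retained for real runs.

## Known limitations

* Ward on consensus distances is an approximation (non-Euclidean input).
* The r-threshold cut under-merges relative to the flat MAP (see above);
  per-replicate, the consensus absorbs the difference.
* Domain scanning and triad anchoring run on synthetic reference data;
  applying them to real proteomes requires substituting real profiles and
  a real fold-annotated reference sequence.
* The expression generator's noise model is i.i.d. Gaussian on log2 values;
  no claim is made about robustness to correlated or heavy-tailed noise.
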