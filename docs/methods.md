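# Methods

This note documents the models, numerical choices and limitations behind
`scnpipe`.  It is written for users who need to know what the pipeline
assumes before trusting its output on real data.

## Genome equipartition

Copy number is read out from read density, so bins must have equal
*expected* read content under a flat (diploid) genome.  A position is
"uniquely mappable" here iff its read-length k-mer contains no N and
occurs exactly once in the genome counting both strands (the k-mer and
its reverse complement jointly occur once, scanning the forward strand).
This exact-match definition stands in for aligner-derived uniqueness; it
is faithful for the toy and simulated genomes the package builds, but
real references should use an externally computed mask (any
per-chromosome boolean vector can be supplied as a
`MappabilityMask`).  Exclusion intervals (e.g. centromeres, where
uniqueness calls are unreliable) are honored at the read-start level and
emitted as their own excluded bins.

Bins are apportioned to chromosomes, and then to the blocks between
exclusions, by largest-remainder on their mappable totals; within a
block, bins take ⌊T/n⌋ or ⌈T/n⌉ mappable starts (global target; earlier
bins take the larger count), falling back to the block-local floor/ceil
when the global counts cannot tile the block.  A bin ends immediately
after its last counted mappable start, and the last bin of a block
extends to the block end, so bins tile the genome and later read
assignment needs no gap handling.  Note a genuine integrality
limitation: with several chromosomes, per-chromosome proportional
quotas and a *global* ⌊T/n⌋/⌈T/n⌉ bin size cannot always coexist (no
integer number of 539/540-start bins tiles a chromosome holding 11,976
starts).  Within any one chromosome or block the balance is exact to
within one start; across chromosomes the deviation is bounded by the
apportionment rounding, which is negligible at realistic bin counts.

## Per-cell profile derivation

The count model is `log(n_b/n̄) = log(c_b/c̄) + B(g_b) + r`.  Parameters
and defaults:

* **pseudocount 1 read** added before logs so zero-count bins stay
  finite (the model is silent on zeros; one read is the smallest
  perturbation that works at any depth);
* **Lowess**: span 0.3 of the data, 3 robustifying iterations, fit in
  log space as the model is written, evaluated with an interpolation
  grid (`delta` = 1% of the GC range) for speed.  Constant-GC input
  degenerates to centering, by construction;
* **segmentation**: recursive splitting with
  circular-binary-segmentation semantics.  The homogeneity statistic is
  the maximum standardized mean difference over all single splits *and*
  over interior arcs with lengths on a geometric grid (ratio 1.25) —
  the arc alternative is what catches an event in the middle of an
  otherwise flat segment, which a pure binary split can dilute away.
  Significance is a within-segment permutation test, alpha 0.02, 100
  permutations, minimum segment width 3 bins, with two shortcuts that
  do not change decisions in practice: statistics beyond
  `sqrt(2 log n) + 3` are accepted outright (the permutation maximum
  concentrates near `sqrt(2 log n)`), and permutations stop early once
  p < alpha is impossible.  An accepted segment splits at the best
  single-split position and both halves are re-examined; a final prune
  merges adjacent segments with numerically equal means, which makes
  segmentation exact on noiseless piecewise-constant input.  Change
  points carry a ±2-bin confidence interval (clipped at chromosome
  ends) — a fixed-width convention, not an inferential interval;
* **quantization**: the multiplier M is scanned on [1, 8] in steps of
  0.01; every near-optimal grid region (within the discretization slack
  `(step · max ratio)²`) is refined by bounded scalar minimization
  before tie-breaking, so an off-grid optimum like M = 7/3 is found
  even when an exact-integer multiple of it sits on the grid.  Ties
  within 1e-9 go to the M nearest 2.0, then the smallest M (diploid
  prior; a flat profile is otherwise ill-posed).  Profiles whose mean
  squared rounding error exceeds 0.10 are flagged for QC.

Two identifiability caveats are inherent to read-depth-only data.
First, a perfectly flat noisy profile cannot reveal its ploidy; the
diploid tie-break applies only at exact ties, so a flat cell that
acquired a spurious split may quantize at M ≈ 1 (uniform CN 1 rather
than 2).  This never creates change points, so clonal inference is
unaffected; the multiplier column of the QC table exposes such cells.
Second, balanced genomes (e.g. pure whole-genome duplications) are
indistinguishable from diploid.

## Collective analysis

Features are stabbing points: per CP sign, the greedy right-endpoint
sweep returns a provably minimal piercing set of the pooled CP
intervals.  A feature is present in a cell iff some CP of that sign has
an interval containing the point; an interval containing several points
marks all of them.  For each cell pair and sign, the contingency table
counts features present in both / A only / B only / neither, and the
one-sided Fisher p (odds ratio > 1) is the hypergeometric upper tail —
computed by `scipy.stats.hypergeom.sf` directly, or through a
precomputed `(F+1)³` tail table when many pairs share one feature count
F (the permutation null re-uses one table across all replicates).
P-values are clamped to [1e-300, 1−1e-16] before combination (default
Fisher's rule, χ²₄; Stouffer's selectable) and the dissimilarity
`ln p_c` is clamped to [ln 1e-300, 0].

The tree is scipy hierarchical clustering (default average linkage).
Dissimilarities are non-positive, so clustering runs on a shifted matrix
and the merge heights are shifted back for the shift-equivariant
linkages (single/complete/average); Ward heights stay on the shifted
scale.  The Newick export places leaves at the most negative merge
height so edge lengths are non-negative.

The null for the FDR permutes entries within every feature row of each
table independently: row marginals are preserved exactly, column
marginals on average.  (Other schemes satisfy the same constraint; this
one is the simplest and is documented rather than asserted to be unique.)
Each permutation recomputes all pairwise dissimilarities and the values
are pooled.  FDR(t) = frac(null ≤ t)/frac(observed ≤ t), monotonized by
a running minimum from the least significant end so that a more negative
dissimilarity never receives a larger FDR, and capped at 1.

Clone calls use: FDR threshold 0.05; feature-sharing condition of ≥ 3
features (pooled across signs) present in ≥ 80% of branch cells;
minimum clone size 3; subclone recursion depth 1.  All are configurable;
the thresholds are conventional rather than derived.  A known boundary
case follows directly from the mathematics: in a perfectly homogeneous
population every feature is present in every cell, each pair's table has
no absent features, Fisher's p is exactly 1 and no branch is cohesive —
feature sharing is evidence only relative to cells that lack the
features.  Equivalently, detection power grows with the excess of the
pooled feature universe over a single cell's feature count; segmentation
jitter, private events and noise cells all contribute that excess in
practice.

## Simulator

The generator emulates the cell-line admixture benchmark: by default 200
cells over 5,000 bins (one synthetic chromosome), of which 10% form a
clone sharing 30 non-overlapping CNV events with integer CN in {1, 3, 4}
and lengths 20–80 bins; the rest are flat diploid.  Counts are
`Poisson(λ · c_b/ploidy · exp(B(g_b)))` with λ = 25 reads/bin (the
recommended working depth is ≥ 20) and an exp-quadratic GC bias
`B = 1.5·(g−ḡ) − 15·(g−ḡ)²` (centered; |B| ≤ ~0.3 over the default GC
range 0.35–0.55).  Options: negative-binomial overdispersion, per-cell
private events (default rate 0 to keep the truth clean), multiple
chromosomes, read-position output for full from-reads runs.

What the simulator does *not* emulate — and hence what passing tests do
not certify about real data: whole-genome-amplification artifacts and
waviness, duplicate reads, mappability errors, segmental artifacts at
centromeres/telomeres, allele-specific signal, and overdispersion
beyond the optional negative binomial.  Real single-cell libraries are
noisier than Poisson; the recommended response is more reads per bin or
fewer bins, not looser thresholds.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the admixture benchmark at
its native size (200 cells × 5,000 bins, 10 seeds) and the remaining
contracts at sizes where their oracles are exhaustive (all 2×2 tables
with margins ≤ 50; exhaustive stabbing minima for ≤ 12 intervals; 20
cells × 1,200 bins for CN recovery; 20 seeds of 100 cells × 200 features
for FDR calibration).  The pipeline determinism check runs a 24-cell ×
400-bin population through the file-based driver twice and with 1 vs 4
workers; per-cell random streams are pre-spawned from the single
top-level seed, which is why worker count cannot change results.
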