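# Methods

## Model and assumptions

`mirbic` treats miRNA target regulation as a biclustering problem on a
binary matrix. Each row is a test-vs-control expression contrast
("condition"), each column a gene from the miRNA's sequence-predicted
background set, and a cell is 1 when the gene's log2 fold change crosses
the quantization threshold in the profile's direction. The working
assumptions are:

- regulation by a miRNA shows up as a near-complete block of 1s: a subset
  of conditions in which a subset of targets respond together;
- real data are noisy, so a useful bicluster tolerates a small fraction of
  zeros (bounded per row and per column rather than globally);
- a 1.3-fold change is strong enough to exclude most measurement noise yet
  weak enough to retain "fine-tuned" targets; 1.5- and 2.0-fold thresholds
  capture progressively stronger regulation at the cost of sensitivity.

Missing fold-change values are treated as neutral (quantized to 0):
absence of evidence of regulation, which keeps matrices dense-rectangular.
A value exactly at the threshold counts as regulated (the inclusive
convention; the boundary case is measure-zero in real data).

## Condition selection

For each condition the enrichment of direction-regulated genes in the
background set is tested with a one-sided hypergeometric upper tail,
universe N = all genes present in the fold-change matrix, K = background
genes present, n = regulated genes in the condition, k = regulated
background genes, p = P(X ≥ k). One test per condition forms the natural
multiple-testing family, so Benjamini–Hochberg adjustment is applied across
all conditions of the matrix for one (miRNA, direction) pair, and
conditions with adjusted p < 0.05 are kept in compendium order (a
determinism aid; no ordering is semantically meaningful here). Conditions
with no regulated genes get p = 1. The down direction is handled fully
symmetrically, with its own enrichment test on down-regulated genes.

## Seed extraction

Seeds are inclusion-maximal all-1 submatrices (maximal bicliques) of at
least `min_seed_rows` × `min_seed_cols` (default 10 × 10).

Two modes exist. **Uncapped** (`max_seeds=None`): the exact BIMAX
divide-and-conquer enumeration — a template row splits the columns into its
1-set and the rest, rows partition by which side they hit, and the second
branch carries a mandatory column set to prevent duplicate reports. Every
leaf is closed against the full matrix, which makes maximality explicit;
the enumeration is tested against a brute-force column-subset oracle on
random matrices up to 12 × 12.

**Capped** (`max_seeds=k`, default 20): one seed per iteration, chosen to
cover the most cells not yet covered by earlier seeds (greedy maximum
coverage). The search anchors on the rows (and, symmetrically, the columns
of the transpose) with the most uncovered 1s, orders the remaining rows by
uncovered overlap with the anchor's support, walks that order while
intersecting supports, keeps the prefix with the largest new-cell count,
and refines the best candidate for up to three passes before closing it
into a maximal biclique. Iteration stops early once no qualifying biclique
adds new coverage. The design rationale: a depth-first enumeration prefix
concentrates all k seeds in near-duplicate fragments of one dense region,
which starves the extension stage of seeds for the other modules; greedy
maximum coverage instead spreads the seed budget over every dense region,
which is what the downstream extension requires. The procedure is fully
deterministic (stable sorts, index tie-breaks) and a cap-k run is a prefix
of a cap-k' run for k' > k.

## Progressive extension

For each zero-proportion threshold t in (0.01, 0.02, …, 0.10), ascending:

- **Addition phase.** Every outside row is scored by its zero fraction over
  the bicluster's current columns, every outside column over its current
  rows; rows and columns compete in one pool. Among candidates with zero
  fraction ≤ t the single best is added — lowest zero fraction, ties broken
  by more 1s in the full profile, then rows before columns, then lowest
  index — and all scores are recomputed. Repeats until no candidate
  qualifies. Best-first addition with full recomputation makes the result
  independent of input layout; the schedule is otherwise unconstrained by
  the method's definition.
- **Removal phase.** While any member row or column has zero fraction > t,
  the single worst is removed (highest zero fraction, then fewest 1s, then
  rows before columns, then lowest index) and scores recomputed. One-at-a-
  time removal avoids the overshoot that batch removal can cause.

A density-1.0 seed is a fixed point of the removal phase at every t, so
extension can never destroy its seed; if removal ever empties the bicluster
the original seed is returned unchanged and a warning logged. At exit every
row and column satisfies the final threshold (zero fraction ≤ 0.10).
Threshold comparisons use an absolute slack of 1e-9 to keep ratio
arithmetic exact.

## Merging and trimming

Extended biclusters are compared by Meet/Min distance
(1 − shared cells / cells of the smaller bicluster), clustered with
average linkage, and the dendrogram is cut strictly below 0.5 (implemented
as a cut at 0.5 − 1e-9; the cutoff is insensitive in the 0.3–0.7 range).
Each cluster becomes the union of its members' rows × union of columns —
deliberately allowed to contain cells outside every member — and is then
trimmed: while any row or column exceeds 10% zeros, the single worst is
removed (same tie-breaks as extension removal). Clusters trimmed to
emptiness are dropped; identical results are deduplicated. Outputs are
sorted by descending cell count, then descending density, then first row
index — an arbitrary but reproducible convention.

## Synthetic-data generator

`simulate.generate_profile` emulates the shape of real binary profiles:
700 × 300 at 20% background density, with 7 planted biclusters whose row
and column sizes are uniform on [20, 80], each carrying an internal zero
fraction drawn uniformly from [1%, 3%], and any two planted biclusters
sharing fewer cells than 20% of the smaller one (enforced by rejection
sampling against the upper bound only — overlap is permitted, not forced;
the denominator convention mirrors Meet/Min). Background refers to cells
outside all rectangles. Rectangles are random index subsets, not contiguous
ranges; all algorithms are invariant to row/column permutation, so nothing
is lost. Noise is realized in reverse placement order: the last-placed
rectangle's draw claims its cells, and earlier rectangles flip only their
unclaimed cells, with flip counts clipped so every rectangle's realized
zero fraction lies exactly within [1%, 3%] — this reconciles "overlap cells
follow the last-placed draw" with a hard per-rectangle noise band.
Replicate seeds are `rng_seed + index` so any single replicate can be
replayed.

What the generator does **not** emulate: correlated noise (real conditions
share platforms and labs), heavy-tailed per-gene variance, condition
duplicates, or the strong row-marginal heterogeneity of real compendia.
Passing the benchmark therefore demonstrates correct recovery of planted
block structure under i.i.d. noise, not performance on real data.

Element-level precision is the fraction of predicted cells inside planted
rectangles, sensitivity the fraction of planted cells covered; an empty
prediction has precision 1 and sensitivity 0 by convention.

## Problem sizes used in tests

The test suite runs the full benchmark at the reference configuration
(50 replicates of 700 × 300) — about 70 s — and uses a down-scaled
configuration (150 × 90, 2 planted biclusters, 3 replicates) for the unit
and property tests. The acceptance script uses the reference configuration
with 50 replicates.

## Known limitations

- The capped seed extractor is a heuristic for maximum-coverage biclique
  selection; it can stop before the cap when its anchored search finds no
  biclique with new coverage even though one may exist.
- On profiles whose planted modules are fully recovered, the benchmark
  sensitivity saturates near the noise ceiling (~99.5% median at the
  reference configuration); the residual ~0.5% are cells of overlap regions
  and rows/columns lost to trimming.
- Gold-standard evaluation treats the GP/GN sets as given; evidence-grade
  curation is out of scope.
- Network filtering uses unweighted degree on the induced prediction
  subgraph; edge scores beyond the admission threshold are ignored.
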