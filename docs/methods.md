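# Methods

This note documents the model each stage implements, the parameters that
matter, the numerical and design choices made where the design was open,
and what the synthetic benchmark does and does not demonstrate.

## Graph model

A variation graph is bidirected: each node has a left and a right side,
edges join sides, and a valid walk enters and leaves a node on opposite
sides, giving every visit an orientation (reverse visits spell the
reverse complement). Haplotypes are explicit named walks; following the
convention of graph formats that derive topology from their haplotypes,
a walk's step adjacencies define (and flag as haplotype-supported) the
edge set. Edges present only on GFA L lines are retained but flagged.
Offsets are 0-based and intervals half-open throughout; GFA segment
names map to dense positive integer ids (numeric names keep their
values), with the original names preserved for output.

## Snarl tree

Two node sides are *separable* when cutting their two nodes into
disconnected half-vertices (every other node contributes an internal
edge between its sides) leaves the component containing both sides free
of either node's opposite half; the nodes of that component, minus the
two boundary nodes, are the snarl contents. A snarl is a separable pair
that is *minimal* — no side inside it is separable with either boundary —
and, as this package's canonicalization of the decomposition's known
non-uniqueness, *traversable*: a valid walk can cross from the start
boundary through the interior to the end boundary. Traversability is
what rejects inside-out boundary pairs (e.g. the pair that "bounds" a
bubble's shared downstream node from within the two alleles), which are
formally separable and minimal but describe no site a walk crosses.

Snarls are accepted smallest-first; candidates that overlap an accepted
snarl without cleanly nesting are dropped. Chains are maximal runs of
nodes and snarls linked through node sides; a bare node is a chain, so
chains partition the node set. Chains are traversed with the lowest node
id first; cyclic chains (a tandem-duplication back edge) are flagged, as
are snarls whose interior admits a repeated node visit.

The decomposition is deliberately brute force — O(V²) component
analyses — as suits desk scale. Above 200 nodes, candidate boundary
pairs are restricted to nodes within 12 hops and contents are capped at
64 side-vertices; this is exact whenever variation sites are bubble-
scale, which holds for every graph the generator produces (sites are
at most `max_indel_length` bases plus flanks). Graphs with wider snarls
should be decomposed with `decompose(graph, max_span=None)` on a larger
`EXHAUSTIVE_NODE_LIMIT`.

## Distance index

Distances are counted in base steps along valid walks: consecutive walk
bases are at distance 1, d(A, A) = 0, orientation is honored (a reverse
position continues leftward), and unreachable is an explicit `None`,
never a sentinel number. Queries run as single-source Dijkstra over a
weighted digraph with two vertices per node (one per traversal
orientation) and edge weight equal to the target node's length; rows are
cached, and a full all-pairs matrix is precomputed when mapping many
reads against graphs of up to 6,000 traversals (float64, at most ~300 MB
at that bound, ~60 MB for the standard fixture). Cycles need no special
treatment: a minimum distance never benefits from looping twice, and
same-traversal queries with a backward offset take the cheapest loop
through the successors. Chain prefix sums (node start offsets including
minimum spans through intervening snarls) and snarl boundary gaps are
derived from the same machinery for the zip-code layer.

## Seeding

The minimizer index is built over the spellings of all haplotype walks:
within every window of `w` consecutive k-mer starts the smallest k-mer
under the order is selected (leftmost on ties; k-mers containing N are
never candidates). The order is a weighted hash: k-mers whose global
occurrence count across all haplotypes exceeds `weight_threshold` sort
after all rarer k-mers, then by an invertible 64-bit mixer
(splitmix64-style finalizer, constants 0xBF58476D1CE4E5B9 and
0x94D049BB133111EB), then by the k-mer itself for a total order.
Canonical k-mers are the lexicographic minimum of a k-mer and its
reverse complement. Occurrences are recorded as oriented graph positions
of the k-mer's first and last base and deduplicated across haplotypes,
so shared sequence is not double-counted. At query time the same
selection runs on the read; minimizers with more than `hard_hit_cap`
index occurrences yield no seeds. A seed's stored position is oriented
along the read: reading onward from it spells the read k-mer exactly,
for either strand, so seeds feed directly into distance queries.

Defaults: k = 19, w = 11 (long reads; k = 29 is a reasonable short-read
profile), weight_threshold = 256, hard_hit_cap = 500. Reads shorter than
k + w − 1 are seeded from their single partial window.

## Zip codes and zip code trees

A zip code is a position's root-to-leaf snarl-tree address: chain levels
carry the child's prefix-sum offset and rank along the chain, snarl
levels the child chain's rank and its boundary gaps, the leaf the node,
its length, the offset in chain direction and the orientation relative
to the chain. Sorting seeds by zip code linearizes them along an
unrolled, acyclic view of the graph.

One tree is built per (root chain, traversal direction): a seed's
direction is its leaf orientation propagated through the chain-in-snarl
and snarl-in-chain orientations up to the root, and seeds that travel
against a tree's direction form the mirror-direction tree of the forest.
Within a tree, seeds sit inside nested chain/snarl brackets in travel
order; child chains of one snarl are siblings. Traversal distances are
accumulated hop by hop — seed to seed within a chain, and across a snarl
through its boundary anchors (last base before entry, first base after
exit) — with each hop an exact minimum distance from the index. Seeds on
sibling chains (alternative alleles) are mutually unreachable in the
traversal.

Because every hop is itself a true minimum distance, any accumulated sum
is bounded below by the true distance (triangle inequality), so the
traversal can never under-report — the property chaining's gap costs
rely on. On acyclic regions traversed without reversals the boundary
anchors lie on every walk between the seeds, making the sums exact.
Across duplications, and for seeds whose orientation conflicts with
their context, the traversal may over-report or declare unreachable
(measured on random mixed-orientation acyclic fixtures: a few tenths of
a percent over-reports, zero under-reports); this conservatism costs
chaining a slightly pessimistic gap, never a corrupted one.

## Chaining

A chain is an ordered seed subset strictly increasing in read offset
with every transition graph-reachable. The score is covered read bases
minus gap costs: coverage of a chained seed is trimmed to
`min(k, Δread)`, and a transition with read gap `r` and graph gap `g`
costs 0 when `|r − g| = 0`, else `a·|r − g| + b·log2|r − g|`
(defaults a = 0.01·k, b = 0.5), infinite when the graph distance is
unreachable or the gap exceeds `max_gap` (10,000). The DP

    score(j) = max(k, max_i score(i) + min(k, r_j − r_i) − gap_cost(i, j))

is exact over each tree's seed order, with predecessors limited to a
`max_lookback` window (64) in tree order — an accuracy/speed knob that
is irrelevant at the seed counts a single read produces. Up to
`top_chains` (4) results are returned, pairwise overlapping by at most
50% of the shorter read interval; ties break toward longer spans and
lower start offsets for determinism.

A production-style two-pass (fragments, then fragment chaining) is
deliberately not used to prune this DP: graph distances are not additive
across arbitrary seed triples, so pre-merging even zero-gap runs can be
lossy, and the exact single pass is cheap at this scale. Maximal
zero-gap runs are instead reported as the fragments of finished chains.
Chains suppressed by the overlap rule that share no seed with an
accepted chain are genuine alternative placements of the same read
stretch; their best score is carried forward as the mapping-quality
competitor.

## Base-level alignment

Between-seed segments align the read interval between consecutive seed
starts to the graph interval between their positions. Haplotype strands
(each walk and its reverse complement) passing through both flanking
positions are tried first: an exact string match costs nothing, and
otherwise a gap-affine wavefront alignment runs in cost space
(mismatch 2(m−x) = 10, gap open −2·go = 12, extend m−2·ge = 3 for the
defaults), converting back via score = (m·(|q|+|t|) − cost)/2 — exact
for gap-affine scoring, with effort proportional to alignment error.
A wavefront exceeding its cost budget is a declared failure, not an
exception. When no haplotype spans a segment, or the problem exceeds
`wfa_max_len` (8192), a banded global aligner runs on the graph itself:
the subgraph between the positions is unrolled into layers by exact walk
length (cycles expand once per layer), and a POA-style affine DP is
restricted to `|query index − layer| ≤ band`.

Tails beyond the first and last seed extend with anchored wavefronts
against haplotype continuations (best-scoring end anywhere, remainder
soft-clipped), falling back to an X-drop extender over the graph that
prunes cells more than X = 20 below the best score seen; left tails are
handled by reversing into the mirror orientation. A local tail aligner
clips a trailing net-loss mismatch rather than aligning it — the correct
behaviour for ends. Pieces are stitched into one walk; the reported
score always equals re-scoring the emitted edit string, aligned plus
clipped read bases always equal the read length, and the walk is
edge-valid by construction.

## Mapping quality and output

MAPQ = clamp(0, 60, round(6·(primary − best competitor)/match)). The
competitor is the best of: extended secondary alignments whose placement
shares at most half its node-bases with the primary (different chains
over one locus converge to identical alignments once tails extend, and
such duplicates are not evidence of ambiguity), and the best suppressed
alternative-placement chain, credited with the same extension gain the
primary realized over its own chain score (an unextended chain's tails
would extend comparably). A read with no competitor maps at 60; an exact
duplicate placement maps at 0. The formula is this package's design; the
tested contract is calibration, not the formula.

Alignments are emitted as GAF: oriented path string (`>`/`<`), path and
read intervals 0-based half-open, residue matches, block length, MAPQ,
with `AS:i` (score), `cg:Z` (CIGAR with =/X) and `cs:Z` (difference
string) tags. Unmapped reads produce no line and are counted in the run
summary. Identical inputs and seeds produce byte-identical output.

## Synthetic pangenomes and evaluation

The generator draws non-overlapping variant sites along a random
backbone — SNV bubbles, insertions/deletions (1–50 bp), inversions (a
node some haplotypes traverse in reverse) and tandem duplications (a
node some haplotypes traverse twice, creating a cycle) — then builds
haplotype walks choosing alleles at probability ½ (haplotype 0 is the
all-reference walk; every alternate allele is forced to be realized so
no node is walk-free), and derives the graph from the walks. Defaults
emulate a human-like density of variation across a small panel: 20 kb
backbone, 8 haplotypes, 4 SNVs per kb, 0.8 indels per kb, 0.1
inversions and duplications per kb.

Reads are sampled uniformly over haplotype spellings and strands with
i.i.d. per-base mismatch/insertion/deletion errors (defaults for the
noisy condition: 2% / 1.5% / 1.5%, a 5% total error rate); read lengths
are normal (mean 1,000, sd 100, floor 100). Each read carries its
error-free source interval. A mapping is judged correct when at least
50% of its reported walk's node-bases fall on node-bases of the true
source slice, computed on per-node base intervals in forward node
coordinates (orientation-blind, so inverted segments count; interval-
based, so a shifted placement on one long node does not). Results are
stratified by MAPQ with cumulative precision per threshold.

What the benchmark does not show: the i.i.d. error model has no
homopolymer or context structure, the variant-site model has no nested
or overlapping variation and no structural variants beyond 50 bp, and
the panel is far smaller than real pangenomes — passing here demonstrates
algorithmic correctness and calibration mechanics, not accuracy on real
instrument data.

## Problem sizes

The shipped test and acceptance runs use: 200 random graphs (up to ~110
nodes) for decomposition equivalence, 50 graphs (up to 200 nodes) and
10,000 ordered position pairs for distance exactness, 10,000+ seed pairs
for zip-tree soundness, 500 instances of up to 12 seeds for chaining
optimality, 1,000 random pairs up to 300 bp for wavefront/DP agreement,
and two 1,000-read mapping experiments (error-free and 5% error) on the
standard 20 kb, 8-haplotype pangenome. These sizes were chosen so the
full suite completes in minutes on one core while every exhaustive
oracle remains tractable.
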