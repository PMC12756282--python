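# Methods

## Profile model and canonical species order

A phylogenetic profile matrix holds genes as rows and species as columns.
Discrete profiles are presence/absence indicators; continuous profiles are
non-negative similarity scores and are accepted only by the metrics whose
definitions extend to them (Pearson, SVD distance) — a `binarize(threshold)`
helper converts them for the discrete-only metrics.

Tree-aware computations require a *tree-ordered* profile: species columns
arranged so that phylogenetically close species are adjacent.  We fix the
canonical order as the depth-first pre-order leaf sequence of the rooted
species tree, following the child order written in the source Newick.  This
choice matters: rotating any internal node's children permutes leaf
adjacencies and hence changes the transition vectors, so reproducibility
requires pinning one convention.  Species present in the tree but absent
from the matrix are ignored; matrix species absent from the tree are an
error (the profile matrix defines the analysis universe).

## The seven comparison measures

| measure | orientation | input | range |
|---|---|---|---|
| Jaccard | distance | discrete | [0, 1] |
| Hamming | distance | discrete | [0, 1] |
| Pearson | similarity | discrete or continuous | [−1, 1] or undefined |
| mutual information | similarity | discrete | ≥ 0 (bits) |
| SVD distance | distance | discrete or continuous | [0, ∞) |
| PCS | similarity | discrete + tree | (−∞, ∞) |
| co-transition | similarity | discrete + tree | [−1, 1] + p-value |

Degenerate-input conventions: Jaccard of two all-absent profiles is 0
(identical), Pearson against a zero-variance profile is NaN and excluded
from ranking and graph building rather than silently zeroed, and mutual
information uses 0·log 0 = 0 with log base 2 so a balanced identical pair
scores exactly 1 bit.

**SVD distance.**  The profile matrix is factored M = U S Vᵀ with the
economy decomposition; the first C = max(1, round(t · n_species)) columns
of U are kept and pairwise Euclidean distances between the retained rows
returned.  Truncation t (default 0.3; the benchmark preset is 0.5)
discards low-variance directions, down-weighting the redundant signal of
clusters of closely related species.  Retained columns are additionally
capped at the numerical rank of M (singular values > s₁·1e−12): null-space
columns of U are arbitrary up to rotation, and keeping them would place
duplicated profiles at nonzero distance.

**Transition vectors.**  For a tree-ordered binary profile of length n,
T1/T2 mark 2-windows (0,1)/(1,0) and T3/T4 mark 4-windows
(0,0,1,1)/(1,1,0,0); every window is evaluated independently per pattern
(a T3 window deliberately also fires the inner T1).  Profiles shorter than
4 have empty T3/T4.

**PCS.**  With m_k the windows where both profiles show pattern k and u_k
the windows where exactly one does, PCS = m1 + m2 + w(m3 + m4) −
p·[u1 + u2 + w(u3 + u4)].  A "match" is counted only where both indicator
vectors equal 1: counting equality of indicators (which also rewards the
shared *absence* of a transition) would grow the score with profile length
rather than with shared evolutionary events.  The literal equality-indicator
reading remains available via `literal=True` for comparison.  Defaults
w = 1.5, p = 0.6; the benchmark/case-study configuration uses p = 0.3.

**Co-transition score.**  Each 2-window has a direction (up, down, none);
c counts windows where both profiles move in the same direction and d
where they oppose.  We use the denominator |Tx − Ty| + |c − d| — the
as-published asymmetric form Tx − Ty + |c − d| can vanish and breaks the
documented [−1, 1] range — and define 0/0 = 0 for transition-free pairs.
The p-value is our interpretation of the method's significance matrix: the
hypergeometric upper tail of observing ≥ c co-occurring transition windows
given Tx and Ty transitions thrown on the n − 1 windows.  Note that under
sparse-transition regimes many unrelated profile pairs tie at score 1
(e.g. both profiles have one concordant transition); the p-value, not the
score, separates them, so score-only rankings of the co-transition measure
are weak on such data by construction.

## Module extraction

Similarities above (distances below) a threshold become edges of an
undirected gene graph; excluded pairs (typically paralogs) are removed
after thresholding and counted.  Four strategies produce modules:
connected components (size ≥ 3, the usual module definition), asynchronous
unweighted label propagation (seeded explicitly, since the algorithm's
node-visit order is stochastic; the seed is stored in the module
provenance), Markov clustering on the full similarity-weighted graph, and
agglomerative hierarchical clustering (average linkage by default; cut by
cluster count or cophenetic distance, or export the full dendrogram).
Modules are renamed `module_1..k` in (size desc, smallest member) order so
outputs are byte-stable.

Markov clustering is implemented in-package: self-loops added, columns
normalised, then alternating expansion (matrix square) and inflation
(elementwise power r > 1, renormalisation) to convergence, clusters read
off the attractor rows with overlaps merged.

Score matrices are converted where a strategy needs a different
orientation: bounded [0, 1] distances via s = 1 − d, unbounded distances
via s = e^(−d), similarities with negative entries shifted by their
minimum for MCL weights; conversely [0, 1] similarities via d = 1 − s,
[−1, 1] via d = (1 − s)/2 and unbounded similarities via d = max − s for
hierarchical clustering.  Each conversion is logged.

`select_threshold` picks a clustering threshold from a positive-pair
benchmark curve: the score at the deepest rank whose cumulative precision
still reaches a target (default 0.3, near the typical inflection of the
precision curve).  Unsupervised alternatives based on modularity or mean
silhouette were evaluated and rejected — with an overwhelming majority of
unclustered singleton genes both quality functions favour coarse,
contaminated partitions.

## Dollo descriptors

Under Dollo parsimony a gene originates once — at the LCA of its presence
species — and may only be lost afterwards.  Annotation propagates leaf
states up by OR within the LCA subtree; the parsimony score counts edges
where a present ancestor leads to an all-absent subtree, which equals the
minimum number of losses (each maximal absent subtree requires at least
one loss, and one suffices).  The exhaustive oracle in the test suite
verifies this equality over every rooted binary tree with up to 6 leaves
and every non-empty profile.

Module descriptors: consensus profile (species present iff ≥ 50% of
module genes are present — the fraction is configurable; no rule is
standard), mean presence count, LCA clade of the consensus presences
(unlabeled internal nodes get deterministic pre-order labels `node_<k>`),
the Dollo score of the consensus, and the mean per-gene Dollo score (the
quantity used by the pair-discrimination benchmark).  Annotated trees
carry per-node mean presence proportions (leaves: fraction of module genes
present; internal nodes: mean over descendant leaves) exported as NHX
`presence` tags rounded to 4 decimals; rounding is the only loss in the
round trip.

## Enrichment

Over-representation only: the hypergeometric upper tail P(X ≥ k) for k of
n module genes carrying a term against K of N population genes, where the
population is all genes of the profile matrix used for clustering (not all
annotated genes — absence of annotation is informative about the
background).  GO-style analysis propagates annotations to is_a/part_of
ancestors by default, corrects per module with Benjamini–Hochberg, and
reports the top 5 terms by ascending FDR (jointly across namespaces by
default; per-namespace optional).  Pathway-style analysis corrects with
Bonferroni across all (module, pathway) tests and keeps rows below
α = 0.05.

## Benchmark harness

Gene pairs are ranked best-first (orientation-aware; NaN dropped;
deterministic lexicographic tie-break), truncated at `max_pairs` (default
10 000), and scored against a positive-pair list: cumulative positives,
per-rank precision, and the trapezoidal area under the curve on axes
x = cumulative positives, y = precision (duplicate x contributes zero
width, so a perfect ranking of P positives has AUC = P − 1).

The parsimony discrimination test reduces each pair to the minimum of its
two genes' Dollo scores (maximum available as an option) and applies a
one-sided Mann–Whitney U test (H1: positive pairs score higher).  When
both samples have fewer than 20 observations the p-value is exact: the
conditional distribution of the rank sum given the observed (possibly
tied) values is computed by dynamic programming over doubled midranks,
equivalent to enumerating all group assignments; larger samples use the
tie-corrected normal approximation.

## Synthetic data generator

The generator emulates the Dollo gene-content process the tree-aware
metrics assume.  A Yule tree (uniform leaf splitting) provides the species
panel.  Each planted module draws a set of loss clades; its base profile
is present everywhere except under them, and each member gene is the base
profile with independent per-species Bernoulli flips (default rate 0.05)
emulating annotation error — incomplete or spurious gene inventories.
Defaults: 50 species, 5 modules of 8 genes, 160 background genes, 3 losses
per module, 10% paralog duplicates (one extra flip each, recorded as
paralog pairs).  Positive pairs are the within-module pairs.

Module loss clades are constrained to be *informative and distinct*:
internal (clade-level) nodes covering at most a quarter of the panel each
(a planted loss is a local, clade-specific event; losing half of all
species leaves almost no transition signal), pairwise disjoint within a
module, not reused across modules (distinct planted signals — on trees too
small to honour this, reuse is allowed as a fallback), with at least 25%
of species surviving overall.  Background genes draw 1..3 disjoint losses
from *all* branches including single leaves, the most common pattern for
genes without shared history.  What the generator does **not** emulate:
horizontal transfer, repeated independent gains, correlated errors between
related species, or lineage-specific rate variation — so passing recovery
tests demonstrate signal detection under the metrics' own model
assumptions, not robustness to model violations.

The recovery experiment scores PCS (w = 1.5, p = 0.3) on a simulated
panel, thresholds the graph at each of ten off-diagonal score quantiles
(0.95–0.999), partitions by seeded label propagation keeping groups of
more than two genes, and reports the adjusted Rand index against the
planted truth over the *whole* gene panel (background genes as singletons
on both sides — the strict planted-partition convention; an ARI restricted
to module genes is also computed).  The grid maximum is an oracle
operating point: it measures whether the score carries enough signal to
recover the planted structure at some threshold.  On the default
conditions the median best ARI over seeds 1–5 is ≈ 0.82, with the five
planted modules typically recovered intact and the residual disagreement
coming from noise-induced member dropout and chance profile collisions
among background genes.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic panels
of 50 species × 200–220 genes with five seeds, sizes at which every
pipeline stage completes in seconds while leaving planted signal clearly
above the noise floor; exhaustive oracles run over all rooted binary trees
with ≤ 6 leaves and all binary vectors of length ≤ 8 (pairs ≤ 6).
Pairwise metric computation is vectorised (matrix products over stacked
transition indicator matrices), making the 200-gene all-vs-all PCS/cotr
matrices essentially instantaneous.  Symmetric score matrices are required
symmetric to 1e−9; undefined cells are NaN throughout and never become
graph edges or ranked pairs.

## Known limitations

- The co-transition p-value is an interpretation (hypergeometric tail);
  the original method's exact definition is not reproduced here.
- Label propagation on graphs with bridge edges between planted groups can
  merge or fragment modules; results should be read at several thresholds.
- The Dollo framework admits no second gain: taxa with horizontal transfer
  violate the model and will inflate loss counts.
- Continuous profiles pass through unnormalised (no best-hit scaling); the
  SVD metric consumes them as given.
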