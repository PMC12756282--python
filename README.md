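# coevoprof

Phylogenetic profile comparison and co-evolution module discovery.

A phylogenetic profile records, for one gene, the presence (1) or absence
(0) of its orthologs across a panel of species.  Genes that work together
— subunits of a complex, members of a pathway — tend to be gained and lost
together over evolution, so genes with similar profiles are candidates for
functional association.  `coevoprof` is a toolkit for the three stages of
such an analysis:

1. **Profile comparison** — seven similarity/distance measures between
   profiles, from plain vector comparisons (Jaccard, Hamming, Pearson,
   mutual information, SVD-based Euclidean distance) to tree-aware scores
   that compare *evolutionary transitions* on a species-tree-ordered
   profile: the phylogenetic co-occurrence score (PCS) and the
   co-transition score.
2. **Module generation** — clustering of the score matrix into groups of
   co-evolving genes by thresholded-graph connected components, label
   propagation, Markov clustering, or hierarchical clustering, with
   optional exclusion of known paralog pairs (whose profiles mirror each
   other by duplication, not co-evolution).
3. **Module description** — Dollo-parsimony descriptors (consensus
   profile, last-common-ancestor clade, minimum loss count), hypergeometric
   term enrichment (GO-style with Benjamini–Hochberg FDR, pathway-style
   with Bonferroni), presence-annotated species trees in extended Newick,
   and profile heatmaps in taxonomic order.

A ranked-pair benchmark harness (precision versus cumulative true
positives, trapezoidal AUC, Mann–Whitney parsimony discrimination) and a
seeded synthetic-data generator with planted co-evolving modules make
every stage testable without any external database.

## The core scores

For a tree-ordered binary profile, transition indicator vectors mark
presence/absence changes between adjacent species: T1 = (0 1), T2 = (1 0),
and the two-species-supported variants T3 = (0 0 1 1), T4 = (1 1 0 0).
With m_k the windows where both profiles show pattern k and u_k the
windows where exactly one does,

    PCS(X, Y) = m1 + m2 + w·(m3 + m4) − p·[u1 + u2 + w·(u3 + u4)]

where the confidence weight *w* (default 1.5) boosts doubly-supported
transitions and the penalty *p* (default 0.6) charges unshared ones.  The
co-transition score, with c concordant and d discordant transition
windows and Tx, Ty the per-profile transition totals, is

    cotr(X, Y) = (c − d) / (|Tx − Ty| + |c − d|)   ∈ [−1, 1]

with a hypergeometric tail p-value for the number of concordant windows.
The Dollo parsimony score of a profile is the minimum number of loss
events explaining it under a single gain at the last common ancestor of
the presence species.

## Worked example

```python
import coevoprof as cp

tree = cp.simulate_tree(50, seed=1)
profiles, truth = cp.simulate_profiles(tree, seed=1, paralog_fraction=0.0)

scores = cp.distance_profiles(profiles, "pcs", tree=tree,
                              confidence=1.5, penalty=0.3)
graph = cp.build_graph(scores, threshold=5.0)
modules = cp.label_propagation_modules(graph, seed=1, min_size=3)
stats = cp.phylogenetic_statistics(modules, profiles, tree)
print(len(modules), "modules")
print(stats[["module_id", "size", "mean_presence_count",
             "lca_clade", "parsimony_score"]])
```

Output:

```
6 modules
  module_id  size  mean_presence_count lca_clade  parsimony_score
0  module_1     8               42.000    node_0                3
1  module_2     8               32.250    node_0                3
2  module_3     8               42.000    node_0                3
3  module_4     8               37.125    node_0                3
4  module_5     5               29.000    node_0                3
5  module_6     3               44.000    node_0                6
```

The first five modules correspond to the five planted in the simulation
(four recovered in full, one with 5 of 8 members; `module_6` is a chance
grouping of three background genes).  Each row describes one module: how
many genes it contains, the average number of species carrying each gene,
the clade label of the consensus profile's last common ancestor (`node_0`
is the root: these genes date back to the panel ancestor), and the
minimum number of loss events explaining the consensus profile under
Dollo parsimony — the planted modules show exactly the 3 losses they were
simulated with.

The same pipeline is available from the shell:

```bash
coevoprof simulate --n-species 50 --seed 1 --out-dir sim/
coevoprof distance --method pcs --profiles sim/profiles.tsv \
    --tree sim/tree.nwk --penalty 0.3 --out pcs.tsv
coevoprof modules --matrix pcs.tsv --method label_propagation \
    --threshold 5 --seed 1 --exclude-pairs sim/paralogs.tsv --out modules.tsv
coevoprof stats --modules modules.tsv --profiles sim/profiles.tsv \
    --tree sim/tree.nwk --out stats.csv
coevoprof plot --modules modules.tsv --profiles sim/profiles.tsv \
    --tree sim/tree.nwk --out-dir heatmaps/
```

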