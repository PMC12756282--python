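"""Extraction of co-evolution modules from a score matrix.

Genes become nodes of an undirected graph; profile similarities above (or
distances below) a threshold become edges.  Modules are extracted by
connected components, asynchronous label propagation, Markov clustering on
the fully connected weighted graph, or agglomerative hierarchical
clustering.  Known paralog pairs can be excluded so that modules reflect
co-evolution rather than shared duplication history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import asyn_lpa_communities
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .metrics import ScoreMatrix

__all__ = [
    "GeneGraph",
    "ModuleSet",
    "build_graph",
    "connected_component_modules",
    "label_propagation_modules",
    "markov_modules",
    "hierarchical_modules",
    "make_modules",
    "select_threshold",
    "to_similarity",
    "to_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneGraph:
    """Thresholded gene graph plus provenance of how it was built."""

    graph: nx.Graph
    metric: str
    threshold: float
    excluded_pairs: int = 0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class ModuleSet:
    """Named, disjoint groups of genes produced by one clustering strategy.

    Modules are ordered by (size descending, lexicographically smallest
    member) and named ``module_1``, ``module_2``, ... so outputs are
    byte-stable.
    """

    modules: list[tuple[str, frozenset]]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        seen: set = set()
        for _, genes in self.modules:
            if seen & genes:
                raise ValueError("modules must be disjoint")
            seen |= genes

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    @property
    def gene_to_module(self) -> dict[str, str]:
        return {g: mid for mid, genes in self.modules for g in genes}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("module_id\tgene_id\n")
            for mid, genes in self.modules:
                for g in sorted(genes):
                    fh.write(f"{mid}\t{g}\n")

    @classmethod
    def read(cls, path, method: str = "file") -> "ModuleSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        groups = [frozenset(sub["gene_id"]) for _, sub in df.groupby("module_id", sort=True)]
        return cls(_order_modules(groups), method=method)


def _order_modules(groups: Iterable[frozenset]) -> list[tuple[str, frozenset]]:
    ordered = sorted(set(groups), key=lambda g: (-len(g), min(g)))
    return [(f"module_{i + 1}", g) for i, g in enumerate(ordered)]


# ------------------------------------------------------------------ graphs

def _edge_passes(score: float, orientation: str, threshold: float) -> bool:
    if not np.isfinite(score):
        return False
    if orientation == "similarity":
        return score >= threshold
    return score <= threshold


def build_graph(
    scores: ScoreMatrix,
    threshold: float,
    exclude_pairs: Optional[set] = None,
) -> GeneGraph:
    """Threshold a square score matrix into an undirected gene graph.

    An edge is kept iff the score passes the orientation-aware threshold
    (similarity >= t, distance <= t).  Undefined (NaN) scores never form
    edges.  ``exclude_pairs`` (e.g. known paralogs) are removed after
    thresholding and their count recorded.
    """
    if not scores.is_square:
        raise ValueError("build_graph requires a square score matrix")
    genes = scores.row_ids
    g = nx.Graph()
    g.add_nodes_from(genes)
    mat = scores.scores
    n = len(genes)
    with np.errstate(invalid="ignore"):
        if scores.orientation == "similarity":
            mask = mat >= threshold
        else:
            mask = mat <= threshold
    mask &= np.isfinite(mat)
    iu = np.triu_indices(n, k=1)
    keep = mask[iu]
    excluded = 0
    exclude_pairs = exclude_pairs or set()
    for i, j in zip(iu[0][keep], iu[1][keep]):
        a, b = genes[i], genes[j]
        if frozenset((a, b)) in exclude_pairs:
            excluded += 1
            continue
        g.add_edge(a, b, weight=float(mat[i, j]))
    return GeneGraph(g, metric=scores.metric, threshold=threshold, excluded_pairs=excluded)


def connected_component_modules(graph: GeneGraph, min_size: int = 3) -> ModuleSet:
    """Connected components of the thresholded graph with at least
    ``min_size`` members (default: strictly more than two genes)."""
    comps = [frozenset(c) for c in nx.connected_components(graph.graph) if len(c) >= min_size]
    return ModuleSet(
        _order_modules(comps),
        method="connected_components",
        params={"threshold": graph.threshold, "min_size": min_size,
                "excluded_pairs": graph.excluded_pairs},
    )


def label_propagation_modules(
    graph: GeneGraph, seed: int, min_size: int = 2
) -> ModuleSet:
    """Asynchronous (unweighted) label propagation communities.

    Label propagation is stochastic in its node-visit order; the explicit
    ``seed`` makes runs reproducible and is recorded in the module
    provenance.  Singletons are not reported by default.
    """
    comms = asyn_lpa_communities(graph.graph, seed=int(seed))
    groups = [frozenset(c) for c in comms if len(c) >= min_size]
    return ModuleSet(
        _order_modules(groups),
        method="label_propagation",
        params={"threshold": graph.threshold, "seed": int(seed),
                "min_size": min_size, "excluded_pairs": graph.excluded_pairs},
    )


# -------------------------------------------------------------------- MCL

def to_similarity(scores: ScoreMatrix) -> np.ndarray:
    """Convert a score matrix to non-negative similarities.

    Bounded distances in [0, 1] map via s = 1 - d; unbounded distances via
    s = exp(-d); similarities with negative entries are shifted by their
    minimum so every weight is >= 0.  NaNs become 0 (no affinity).
    """
    mat = scores.scores.astype(float).copy()
    nan = ~np.isfinite(mat)
    mat[nan] = 0.0
    if scores.orientation == "distance":
        if np.nanmax(mat) <= 1.0:
            sim = 1.0 - mat
            logger.info("distance->similarity via s = 1 - d (%s)", scores.metric)
        else:
            sim = np.exp(-mat)
            logger.info("distance->similarity via s = exp(-d) (%s)", scores.metric)
    else:
        sim = mat
        lo = sim.min()
        if lo < 0:
            sim = sim - lo
            logger.info("similarity shifted by %+.4g to be non-negative (%s)",
                        -lo, scores.metric)
    sim[nan] = 0.0
    return sim


def to_distance(scores: ScoreMatrix) -> np.ndarray:
    """Convert a score matrix to a distance matrix with zero diagonal.

    Distances pass through; [0,1] similarities map via d = 1 - s; [-1,1]
    similarities via d = (1 - s)/2; unbounded similarities via
    d = max(s) - s.  NaNs become the largest distance observed.
    """
    mat = scores.scores.astype(float).copy()
    finite = np.isfinite(mat)
    if scores.orientation == "distance":
        dist = mat.copy()
    else:
        lo = mat[finite].min() if finite.any() else 0.0
        hi = mat[finite].max() if finite.any() else 1.0
        if lo >= 0 and hi <= 1:
            dist = 1.0 - mat
        elif lo >= -1 and hi <= 1:
            dist = (1.0 - mat) / 2.0
        else:
            dist = hi - mat
    worst = dist[np.isfinite(dist)].max() if np.isfinite(dist).any() else 1.0
    dist[~np.isfinite(dist)] = worst
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def _mcl(matrix: np.ndarray, inflation: float, expansion: int = 2,
         max_iter: int = 200, tol: float = 1e-8, prune: float = 1e-6) -> list[frozenset]:
    """Markov clustering on a non-negative affinity matrix (index clusters).

    Alternates expansion (matrix power) and inflation (elementwise power
    plus column renormalisation) until the flow matrix is stable, then
    reads clusters off the attractor rows.
    """
    m = matrix.astype(float).copy()
    np.fill_diagonal(m, m.diagonal() + 1.0)  # self loops stabilise the flow
    colsum = m.sum(0)
    colsum[colsum == 0] = 1.0
    m = m / colsum
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune] = 0.0
        colsum = m.sum(0)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            break
    attractors = np.where(m.diagonal() > 1e-9)[0]
    clusters: list[set] = []
    for a in attractors:
        members = set(np.where(m[a] > 1e-9)[0]) | {int(a)}
        merged = False
        for cl in clusters:
            if cl & members:
                cl |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # merging can create new overlaps; resolve to a flat disjoint partition
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return [frozenset(c) for c in clusters]


def markov_modules(
    scores: ScoreMatrix,
    inflation: float = 2.0,
    exclude_pairs: Optional[set] = None,
    min_size: int = 2,
) -> ModuleSet:
    """Markov clustering of the fully connected similarity-weighted graph.

    Distances are converted to similarities first (see
    :func:`to_similarity`); excluded pairs get zero weight.  Clusters with
    fewer than ``min_size`` genes are dropped.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    if not scores.is_square:
        raise ValueError("markov_modules requires a square score matrix")
    genes = scores.row_ids
    sim = to_similarity(scores)
    np.fill_diagonal(sim, 0.0)
    excluded = 0
    for pair in exclude_pairs or set():
        a, b = tuple(pair)
        if a in genes and b in genes:
            i, j = genes.index(a), genes.index(b)
            sim[i, j] = sim[j, i] = 0.0
            excluded += 1
    clusters = _mcl(sim, inflation=inflation)
    groups = [frozenset(genes[i] for i in c) for c in clusters if len(c) >= min_size]
    # genes with no affinity at all form spurious singleton attractor groups
    return ModuleSet(
        _order_modules(groups),
        method="mcl",
        params={"inflation": inflation, "min_size": min_size, "excluded_pairs": excluded},
    )


# ------------------------------------------------------------- hierarchical

def hierarchical_modules(
    scores: ScoreMatrix,
    mode: str,
    value=None,
    linkage: str = "average",
    min_size: int = 1,
):
    """Agglomerative clustering of genes on the (derived) distance matrix.

    ``mode="n_clusters"`` cuts the dendrogram into ``value`` flat clusters,
    ``mode="cut_distance"`` cuts at cophenetic distance ``value``, and
    ``mode="full_dendrogram"`` returns a nested-list encoding of the whole
    dendrogram instead of a ModuleSet.
    """
    if not scores.is_square:
        raise ValueError("hierarchical_modules requires a square score matrix")
    genes = scores.row_ids
    dist = to_distance(scores)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if mode == "full_dendrogram":
        tree = hierarchy.to_tree(z)

        def encode(node):
            if node.is_leaf():
                return genes[node.id]
            return [encode(node.left), encode(node.right), round(float(node.dist), 12)]

        return encode(tree)
    if mode == "n_clusters":
        k = int(value)
        if k > len(genes):
            raise ValueError(f"n_clusters={k} exceeds number of genes ({len(genes)})")
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    elif mode == "cut_distance":
        labels = hierarchy.fcluster(z, t=float(value), criterion="distance")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[int, set] = {}
    for gene, lab in zip(genes, labels):
        groups.setdefault(int(lab), set()).add(gene)
    kept = [frozenset(g) for g in groups.values() if len(g) >= min_size]
    return ModuleSet(
        _order_modules(kept),
        method="hierarchical",
        params={"mode": mode, "value": value, "linkage": linkage, "min_size": min_size},
    )


# ------------------------------------------------------------- front door

def make_modules(
    scores: ScoreMatrix,
    method: str = "label_propagation",
    threshold: Optional[float] = None,
    exclude_pairs: Optional[set] = None,
    seed: int = 0,
    min_size: Optional[int] = None,
    inflation: float = 2.0,
    **kwargs,
) -> ModuleSet:
    """One-call module extraction dispatching to the chosen strategy."""
    if method in ("cc", "connected_components"):
        graph = build_graph(scores, threshold, exclude_pairs)
        return connected_component_modules(graph, min_size=min_size or 3)
    if method == "label_propagation":
        graph = build_graph(scores, threshold, exclude_pairs)
        return label_propagation_modules(graph, seed=seed, min_size=min_size or 2)
    if method == "mcl":
        return markov_modules(scores, inflation=inflation,
                              exclude_pairs=exclude_pairs, min_size=min_size or 2)
    if method == "hierarchical":
        return hierarchical_modules(scores, min_size=min_size or 1, **kwargs)
    raise ValueError(f"unknown clustering method {method!r}")


def select_threshold(
    scores: ScoreMatrix,
    positives: set,
    target_precision: float = 0.3,
    max_pairs: int = 10_000,
    exclude_pairs: Optional[set] = None,
) -> float:
    """Pick an edge threshold from the positive-pair precision curve.

    Pairs are ranked best-first and the threshold is the score of the
    deepest rank at which the cumulative precision against the known
    positive pairs still reaches ``target_precision`` — the same logic
    used to pick a clustering threshold from a benchmark curve near its
    inflection.
    """
    from .benchmark import precision_curve, rank_pairs

    ranked = rank_pairs(scores, exclude_pairs=exclude_pairs)
    curve = precision_curve(ranked, positives, max_pairs=max_pairs)
    ok = curve.table[curve.table["precision"] >= target_precision]
    if ok.empty:
        raise ValueError(
            f"precision never reaches {target_precision}; no usable threshold"
        )
    return float(ok["score"].iloc[-1])
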