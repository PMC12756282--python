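"""Hypergeometric term enrichment of modules.

Over-representation of annotation terms (GO terms, KEGG pathways) within a
module is tested against the background of all genes in the profile matrix
used for clustering.  GO results are corrected per module with the
Benjamini-Hochberg FDR and the top terms reported; KEGG results are
corrected family-wise with Bonferroni and filtered at a significance
cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .clustering import ModuleSet

__all__ = [
    "AnnotationMap",
    "hypergeom_tail",
    "bh_fdr",
    "go_enrichment",
    "kegg_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Gene -> term annotations plus optional ontology structure.

    ``parents`` holds is_a/part_of edges (term -> set of parent terms) used
    for annotation propagation; ``term_names`` and ``namespaces`` are
    cosmetic metadata.
    """

    gene_to_terms: dict[str, set]
    term_names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path, obo_path=None) -> "AnnotationMap":
        """Two-column (gene, term) TSV, optionally with an OBO ontology for
        term names, namespaces and parent edges."""
        gene_to_terms: dict[str, set] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed annotation at line {lineno}: {line!r}")
                gene, term = parts[0], parts[1]
                gene_to_terms.setdefault(gene, set()).add(term)
        ann = cls(gene_to_terms)
        if obo_path is not None:
            ann._load_obo(obo_path)
        return ann

    def _load_obo(self, obo_path) -> None:
        import obonet

        graph = obonet.read_obo(obo_path)
        for term, data in graph.nodes(data=True):
            self.term_names[term] = data.get("name", term)
            self.namespaces[term] = data.get("namespace", "")
        for child, parent, key in graph.edges(keys=True):
            if key in ("is_a", "part_of"):
                self.parents.setdefault(child, set()).add(parent)
        known = set(self.term_names)
        for gene, terms in self.gene_to_terms.items():
            unknown = terms - known
            if unknown:
                logger.warning(
                    "gene %s has terms absent from the ontology (kept unpropagated): %s",
                    gene, sorted(unknown),
                )

    def ancestors(self, term: str) -> set:
        """All ancestor terms reachable through is_a/part_of edges."""
        out: set = set()
        stack = [term]
        while stack:
            for parent in self.parents.get(stack.pop(), ()):
                if parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def propagated(self) -> dict[str, set]:
        """Gene -> terms including every ancestor of every direct term."""
        out = {}
        for gene, terms in self.gene_to_terms.items():
            full = set(terms)
            for t in terms:
                full |= self.ancestors(t)
            out[gene] = full
        return out


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn): the chance of seeing at least k marked genes in the module."""
    if not (0 <= k <= min(K, n) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _module_term_counts(genes, gene_terms, population_terms):
    counts: dict[str, int] = {}
    for g in genes:
        for t in gene_terms.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    return counts


def go_enrichment(
    modules: ModuleSet,
    annotations: AnnotationMap,
    population: Iterable[str],
    top_k: int = 5,
    propagate: bool = True,
    per_namespace: bool = False,
) -> pd.DataFrame:
    """Per-module GO over-representation with BH-FDR correction.

    The background is the full gene population of the profile matrix.  With
    ``propagate`` (default) annotations are extended to ancestor terms via
    is_a/part_of before testing.  For each module, every term annotated to
    at least one member is tested, FDR-corrected across that module's
    tests, and the ``top_k`` terms by ascending FDR (ties by ascending p,
    then term id) are reported — jointly across namespaces by default, or
    per namespace with ``per_namespace``.
    """
    population = list(dict.fromkeys(population))
    pop_set = set(population)
    gene_terms = annotations.propagated() if propagate else annotations.gene_to_terms
    gene_terms = {g: t for g, t in gene_terms.items() if g in pop_set}
    pop_counts = _module_term_counts(population, gene_terms, None)
    n_pop = len(population)

    rows = []
    for mid, genes in modules:
        missing = sorted(set(genes) - pop_set)
        if missing:
            raise ValueError(f"module {mid} genes absent from population: {missing}")
        counts = _module_term_counts(sorted(genes), gene_terms, None)
        if not counts:
            continue
        terms = sorted(counts)
        pvals = [
            hypergeom_tail(counts[t], pop_counts[t], len(genes), n_pop) for t in terms
        ]
        fdr = bh_fdr(pvals)
        sub = pd.DataFrame(
            {
                "module_id": mid,
                "term": terms,
                "name": [annotations.term_names.get(t, t) for t in terms],
                "namespace": [annotations.namespaces.get(t, "") for t in terms],
                "k": [counts[t] for t in terms],
                "K": [pop_counts[t] for t in terms],
                "n": len(genes),
                "N": n_pop,
                "p_value": pvals,
                "fdr": fdr,
            }
        ).sort_values(["fdr", "p_value", "term"], kind="mergesort")
        if per_namespace:
            sub = sub.groupby("namespace", sort=False, group_keys=False).head(top_k)
        else:
            sub = sub.head(top_k)
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["module_id", "term", "name", "namespace", "k", "K", "n", "N",
                     "p_value", "fdr"]
        )
    return pd.concat(rows, ignore_index=True)


def kegg_enrichment(
    modules: ModuleSet,
    pathway_map: AnnotationMap,
    population: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Module x pathway over-representation with Bonferroni control.

    Every (module, pathway-with-a-hit) combination is tested; raw p-values
    are multiplied by the total number of tests and only rows with a
    corrected value below ``alpha`` are kept.
    """
    population = list(dict.fromkeys(population))
    pop_set = set(population)
    gene_terms = {g: t for g, t in pathway_map.gene_to_terms.items() if g in pop_set}
    pop_counts = _module_term_counts(population, gene_terms, None)
    n_pop = len(population)

    tests = []
    for mid, genes in modules:
        missing = sorted(set(genes) - pop_set)
        if missing:
            raise ValueError(f"module {mid} genes absent from population: {missing}")
        counts = _module_term_counts(sorted(genes), gene_terms, None)
        for term in sorted(counts):
            p = hypergeom_tail(counts[term], pop_counts[term], len(genes), n_pop)
            tests.append((mid, term, counts[term], pop_counts[term], len(genes), p))
    cols = ["module_id", "term", "name", "k", "K", "n", "N", "p_value", "bonferroni"]
    if not tests:
        return pd.DataFrame(columns=cols)
    n_tests = len(tests)
    rows = [
        {
            "module_id": mid,
            "term": term,
            "name": pathway_map.term_names.get(term, term),
            "k": k,
            "K": kk,
            "n": n,
            "N": n_pop,
            "p_value": p,
            "bonferroni": min(1.0, p * n_tests),
        }
        for mid, term, k, kk, n, p in tests
    ]
    df = pd.DataFrame(rows, columns=cols)
    df = df[df["bonferroni"] < alpha]
    return df.sort_values(["bonferroni", "p_value", "module_id", "term"],
                          kind="mergesort").reset_index(drop=True)
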