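"""Dollo-parsimony descriptors of profiles and modules on the species tree.

Under a Dollo model a gene is gained exactly once — at the last common
ancestor (LCA) of the species that carry it — and may subsequently be lost
any number of times.  The parsimony score of a profile is therefore the
minimum number of loss events (edges where a present ancestor leads to a
fully absent subtree) needed to explain it.  For modules, the same
machinery yields a consensus profile, per-node mean presence proportions,
and an annotated tree exported in extended Newick (NHX).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .clustering import ModuleSet
from .io import ProfileMatrix
from .tree import SpeciesTree, TreeNode

__all__ = [
    "DolloAnnotation",
    "dollo_annotate",
    "parsimony_score",
    "module_consensus",
    "phylogenetic_statistics",
    "tree_annotation",
    "read_annotated_tree",
]

logger = logging.getLogger(__name__)

Profile = Union[Mapping[str, int], pd.Series]


@dataclass
class DolloAnnotation:
    """Result of Dollo ancestral-state annotation for one profile.

    ``states`` maps each node of the (pruned) tree to its reconstructed
    presence state; nodes outside the LCA subtree carry 0.  ``loss_count``
    is the number of 1 -> 0 edges inside the LCA subtree, i.e. the Dollo
    parsimony score.
    """

    tree: SpeciesTree
    states: dict[TreeNode, int]
    loss_count: int
    lca_node: TreeNode

    @property
    def lca_label(self) -> Optional[str]:
        return self.lca_node.name


def _as_presence_map(profile: Profile) -> dict[str, int]:
    if isinstance(profile, pd.Series):
        return {str(k): int(v) for k, v in profile.items()}
    return {str(k): int(v) for k, v in profile.items()}


def dollo_annotate(profile: Profile, tree: SpeciesTree) -> DolloAnnotation:
    """Annotate the species tree with Dollo ancestral states for a profile.

    Leaves take the profile value; each internal node inside the subtree of
    the presence LCA is 1 iff at least one descendant leaf is present.
    When the profile covers only part of the tree, the tree is pruned to
    the profile's species first and unlabeled internal nodes of the pruned
    copy get deterministic pre-order labels; a full-coverage profile is
    annotated on the input tree as-is (pre-label it if LCA clade labels
    are wanted).
    """
    pmap = _as_presence_map(profile)
    present = [s for s, v in pmap.items() if v == 1]
    if not present:
        raise ValueError("all-absent profile: no presences to anchor the LCA")
    if set(pmap) == set(tree.leaf_names):
        work = tree  # no pruning needed; the input tree is used as-is
    else:
        work = tree.prune_to(pmap.keys())
        work.label_internal()
    lca = work.mrca(present) if len(present) > 1 else work.find_leaf(present[0])
    states: dict[TreeNode, int] = {}
    in_lca: set = set(lca.preorder())
    for node in work.postorder():
        if node not in in_lca:
            states[node] = 0
        elif node.is_leaf:
            states[node] = pmap[node.name]
        else:
            states[node] = int(any(states[c] for c in node.children))
    losses = 0
    for node in in_lca:
        if states[node] == 1:
            losses += sum(1 for c in node.children if states[c] == 0)
    return DolloAnnotation(work, states, losses, lca)


def parsimony_score(profile: Profile, tree: SpeciesTree) -> int:
    """Minimum number of losses explaining the profile under a single gain
    at the presence LCA (the Dollo parsimony score)."""
    return dollo_annotate(profile, tree).loss_count


def module_consensus(
    module: Iterable[str], profiles: ProfileMatrix, fraction: float = 0.5
) -> pd.Series:
    """Consensus profile of a module: species present iff at least
    ``fraction`` of the module's genes are present there."""
    genes = list(module)
    if not genes:
        raise ValueError("empty module has no consensus")
    missing = sorted(set(genes) - set(profiles.gene_ids))
    if missing:
        raise ValueError(f"module genes missing from profiles: {missing}")
    sub = profiles.data.loc[genes]
    return (sub.mean(axis=0) >= fraction).astype(np.int8)


def phylogenetic_statistics(
    modules: ModuleSet,
    profiles: ProfileMatrix,
    tree: SpeciesTree,
    consensus_fraction: float = 0.5,
) -> pd.DataFrame:
    """Descriptor table with one row per module.

    Columns: module size, consensus profile (0/1 string in the matrix's
    species order), mean number of species with orthologs per gene, the
    label of the consensus-presence LCA clade, the Dollo parsimony score of
    the consensus profile, and the mean per-gene parsimony score (used by
    the pair-discrimination benchmark).
    """
    tree = tree.copy()
    tree.label_internal()
    rows = []
    for mid, genes in modules:
        sub = profiles.data.loc[sorted(genes)]
        consensus = module_consensus(genes, profiles, fraction=consensus_fraction)
        mean_presence = float(sub.sum(axis=1).mean())
        if consensus.sum() == 0:
            logger.warning("module %s has an all-absent consensus profile", mid)
            lca_label, pars = None, np.nan
        else:
            ann = dollo_annotate(consensus, tree)
            lca_label, pars = ann.lca_label, ann.loss_count
        gene_scores = [
            parsimony_score(sub.loc[g], tree) for g in sub.index if sub.loc[g].sum() > 0
        ]
        rows.append(
            {
                "module_id": mid,
                "size": len(genes),
                "consensus": "".join(str(int(v)) for v in consensus),
                "mean_presence_count": mean_presence,
                "lca_clade": lca_label,
                "parsimony_score": pars,
                "mean_gene_parsimony": float(np.mean(gene_scores)) if gene_scores else np.nan,
            }
        )
    return pd.DataFrame(rows)


def tree_annotation(
    module: Iterable[str], profiles: ProfileMatrix, tree: SpeciesTree
) -> tuple[SpeciesTree, str]:
    """Annotate the species tree with per-node module presence proportions.

    Each leaf gets the fraction of module genes present in that species;
    each internal node the mean over its descendant leaves.  Returns the
    annotated tree and its extended-Newick (NHX) serialization with
    ``presence`` tags rounded to 4 decimals.
    """
    genes = list(module)
    if not genes:
        raise ValueError("empty module cannot be annotated")
    sub = profiles.data.loc[genes]
    proportions = sub.mean(axis=0)
    work = tree.prune_to(profiles.species_ids)
    work.label_internal()
    for node in work.postorder():
        if node.is_leaf:
            node.annotation = float(proportions[node.name])
        else:
            leaves = node.leaves()
            node.annotation = float(np.mean([l.annotation for l in leaves]))
    return work, work.to_newick(annotations=True)


def read_annotated_tree(path) -> tuple[SpeciesTree, dict[str, float]]:
    """Parse an NHX-annotated tree; returns the tree and a name -> presence
    map (round-trip counterpart of :func:`tree_annotation`)."""
    tree = SpeciesTree.read(path)
    ann = {n.name: n.annotation for n in tree.preorder() if n.annotation is not None}
    return tree, ann
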