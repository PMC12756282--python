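"""Heatmap rendering of module profiles in taxonomic order.

Determinism is promised at the level of the rendered cell matrix and
column/row ordering, not PNG bytes (those depend on the renderer version);
:func:`profiles_heatmap` therefore returns the matrix it drew.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable, Mapping, Optional

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .clustering import ModuleSet
from .io import ProfileMatrix, tree_order
from .tree import SpeciesTree

__all__ = ["profiles_heatmap", "plot_modules"]

logger = logging.getLogger(__name__)

_PALETTE = "tab10"


def profiles_heatmap(
    module: Iterable[str],
    profiles: ProfileMatrix,
    tree: Optional[SpeciesTree] = None,
    order_by_tree: bool = False,
    clade_map: Optional[Mapping[str, str]] = None,
    out: Optional[str] = None,
) -> np.ndarray:
    """Render one module's profiles as a genes x species heatmap.

    With ``order_by_tree`` the species columns follow the depth-first
    pre-order leaf sequence of the tree; ``clade_map`` adds a colored
    taxonomic strip above the matrix (colors assigned from a fixed palette
    in clade-name sorted order).  Returns the plotted cell matrix.
    """
    genes = sorted(module)
    missing = sorted(set(genes) - set(profiles.gene_ids))
    if missing:
        raise ValueError(f"module genes missing from profiles: {missing}")
    sub = profiles.subset(genes)
    if order_by_tree:
        if tree is None:
            raise ValueError("order_by_tree requires a species tree")
        sub = tree_order(sub, tree)
    mat = sub.values.astype(float)

    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * sub.n_species), max(2, 0.3 * sub.n_genes + 1))
    )
    sns.heatmap(
        sub.data.astype(float),
        ax=ax,
        cmap="Greys" if profiles.mode == "discrete" else "viridis",
        cbar=profiles.mode != "discrete",
        vmin=0,
        vmax=1 if profiles.mode == "discrete" else None,
        linewidths=0.0,
    )
    ax.set_xlabel("species")
    ax.set_ylabel("genes")
    if clade_map is not None:
        clades = sorted({clade_map[s] for s in sub.species_ids if s in clade_map})
        colors = sns.color_palette(_PALETTE, max(len(clades), 1))
        color_of = dict(zip(clades, colors))
        for i, s in enumerate(sub.species_ids):
            clade = clade_map.get(s)
            if clade is not None:
                ax.add_patch(
                    plt.Rectangle((i, -0.6), 1, 0.5, clip_on=False,
                                  color=color_of[clade], linewidth=0)
                )
        ax.set_title(" / ".join(clades), fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
    plt.close(fig)
    return mat


def plot_modules(
    modules: ModuleSet,
    profiles: ProfileMatrix,
    tree: Optional[SpeciesTree] = None,
    out_dir: str = ".",
    clade_map: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """One PNG per module under ``out_dir`` plus an index file; returns the
    list of written image paths."""
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    written = []
    if not len(modules):
        logger.warning("empty module set: nothing to plot")
    for mid, genes in modules:
        path = os.path.join(out_dir, f"{mid}.png")
        profiles_heatmap(
            genes, profiles, tree=tree, order_by_tree=tree is not None,
            clade_map=clade_map, out=path,
        )
        written.append(path)
    index = os.path.join(out_dir, "index.json")
    with open(index, "w") as fh:
        json.dump({"images": [os.path.basename(p) for p in written]}, fh, indent=2)
    return written
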