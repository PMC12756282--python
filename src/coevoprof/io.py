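"""Reading, validating and writing phylogenetic profile matrices and the
auxiliary inputs (species trees, gene-pair lists).

A phylogenetic profile matrix has genes as rows and organisms as columns.
Values are either discrete presence/absence (0/1) or continuous non-negative
similarity scores.  The canonical species order for tree-aware metrics is
the depth-first pre-order leaf sequence of the species tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .tree import SpeciesTree, read_tree  # noqa: F401  (re-exported)

__all__ = [
    "ProfileMatrix",
    "read_profiles",
    "write_profiles",
    "read_tree",
    "tree_order",
    "read_pairs",
    "write_pairs",
    "binarize",
]

logger = logging.getLogger(__name__)

DISCRETE = "discrete"
CONTINUOUS = "continuous"


@dataclass
class ProfileMatrix:
    """Gene x species profile matrix.

    Parameters
    ----------
    data:
        DataFrame with gene ids as index and species ids as columns.
    mode:
        ``"discrete"`` (all values in {0, 1}) or ``"continuous"``
        (finite, non-negative reals).
    """

    data: pd.DataFrame
    mode: str = DISCRETE

    def __post_init__(self):
        if self.mode not in (DISCRETE, CONTINUOUS):
            raise ValueError(f"unknown mode {self.mode!r}")
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene id: {dup[0]!r}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate species id: {dup[0]!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("profile matrix contains non-numeric cells")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing cell at gene {self.data.index[r]!r}, "
                f"species {self.data.columns[c]!r}"
            )
        if self.mode == DISCRETE:
            if not np.isin(values, (0, 1)).all():
                bad = values[~np.isin(values, (0, 1))][0]
                raise ValueError(f"value {bad!r} not in {{0,1}} under discrete mode")
            self.data = self.data.astype(np.int8)
        else:
            if not np.isfinite(values).all() or (values < 0).any():
                raise ValueError("continuous profiles must be finite and >= 0")
            self.data = self.data.astype(float)

    # ----------------------------------------------------------------- views
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    def profile(self, gene_id: str) -> pd.Series:
        return self.data.loc[gene_id]

    def subset(self, gene_ids: Iterable[str]) -> "ProfileMatrix":
        return ProfileMatrix(self.data.loc[list(gene_ids)], mode=self.mode)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProfileMatrix({self.n_genes} genes x {self.n_species} species, {self.mode})"


def read_profiles(path, delimiter: str = "auto", mode: str = "auto") -> ProfileMatrix:
    """Read a profile matrix from comma- or tab-separated text.

    The header row holds species ids and the first column holds gene ids.
    ``delimiter="auto"`` picks tab if the header contains one, else comma.
    ``mode="auto"`` selects discrete iff every value is 0 or 1.
    """
    with open(path) as fh:
        header = fh.readline()
    if delimiter == "auto":
        sep = "\t" if "\t" in header else ","
    elif delimiter in ("tab", "\t"):
        sep = "\t"
    elif delimiter in ("comma", ","):
        sep = ","
    else:
        raise ValueError(f"unknown delimiter {delimiter!r}")

    species = [s.strip() for s in header.rstrip("\n").split(sep)[1:]]
    seen: set[str] = set()
    for s in species:
        if s in seen:
            raise ValueError(f"duplicate species id: {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = species
    df.index = df.index.astype(str)
    non_num = df.select_dtypes(exclude="number").columns
    if len(non_num):
        col = non_num[0]
        bad = df[col][~df[col].astype(str).str.match(r"^-?\d+(\.\d+)?([eE][+-]?\d+)?$")]
        row = bad.index[0] if len(bad) else df.index[0]
        raise ValueError(f"non-numeric cell at gene {row!r}, species {col!r}")

    if mode == "auto":
        mode = DISCRETE if np.isin(df.to_numpy(), (0, 1)).all() else CONTINUOUS
    return ProfileMatrix(df, mode=mode)


def write_profiles(profiles: ProfileMatrix, path, delimiter: str = "tab") -> None:
    sep = "\t" if delimiter in ("tab", "\t") else ","
    profiles.data.to_csv(path, sep=sep)


def tree_order(profiles: ProfileMatrix, tree: SpeciesTree) -> ProfileMatrix:
    """Reorder species columns to the depth-first pre-order leaf sequence of
    the tree, restricted to the species present in the profile matrix.

    Tree leaves absent from the matrix are ignored; matrix species absent
    from the tree are an error.
    """
    have = set(profiles.species_ids)
    missing = sorted(have - set(tree.leaf_names))
    if missing:
        raise ValueError(f"profile species missing from tree: {missing}")
    order = [name for name in tree.leaf_names if name in have]
    return ProfileMatrix(profiles.data[order], mode=profiles.mode)


def binarize(profiles: ProfileMatrix, threshold: float) -> ProfileMatrix:
    """Threshold a continuous matrix into presence/absence (>= threshold -> 1)."""
    data = (profiles.data >= threshold).astype(np.int8)
    return ProfileMatrix(data, mode=DISCRETE)


# ------------------------------------------------------------------ pairs

def read_pairs(path) -> set[frozenset]:
    """Read an unordered, de-duplicated set of gene pairs from two-column
    text (whitespace or tab separated).  Self-pairs are dropped with a
    warning; malformed lines are an error."""
    pairs: set[frozenset] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed pair at line {lineno}: {line!r}")
            a, b = parts
            if a == b:
                logger.warning("dropping self-pair %r at line %d", a, lineno)
                continue
            pairs.add(frozenset((a, b)))
    return pairs


def write_pairs(pairs: Iterable[frozenset], path) -> None:
    rows = sorted(tuple(sorted(p)) for p in pairs)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
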