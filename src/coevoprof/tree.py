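"""Rooted species trees: Newick parsing, leaf ordering, LCA queries, NHX export.

The species tree fixes the canonical column order of every tree-aware
computation.  Child order as written in the source Newick is preserved,
because rotating children changes the adjacency of leaves and therefore the
transition vectors derived from a tree-ordered profile.
"""

from __future__ import annotations

import io
import re
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["TreeNode", "SpeciesTree", "read_tree"]

_SAFE_LABEL = re.compile(r"^[\w.\-|]+$")


class TreeNode:
    """A node of a rooted tree. Leaves carry species names; internal nodes
    may carry labels and a float annotation (mean presence)."""

    __slots__ = ("name", "children", "parent", "annotation")

    def __init__(self, name: Optional[str] = None):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.annotation: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"TreeNode({self.name!r}, children={len(self.children)})"


class SpeciesTree:
    """Rooted species tree with uniquely named leaves.

    The depth-first pre-order leaf sequence (left to right as written in the
    Newick) is the canonical species order used by tree-ordered profiles.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in root.leaves()]
        dup = _first_duplicate(names)
        if dup is not None:
            raise ValueError(f"duplicate leaf name in tree: {dup!r}")
        if any(n is None for n in names):
            raise ValueError("every leaf must be named")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                extract_comment_metadata=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            if "Duplicate taxon" in str(exc):
                raise ValueError(f"duplicate leaf name in tree: {exc}") from exc
            raise ValueError(f"unparseable Newick: {exc}") from exc
        root = _convert(dtree.seed_node)
        return cls(root)

    @classmethod
    def read(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, annotations: bool = False) -> str:
        """Serialize to Newick; with ``annotations=True`` emit NHX
        ``presence`` tags (4 decimals) for every annotated node."""
        buf = io.StringIO()
        _write_newick(self.root, buf, annotations)
        buf.write(";")
        return buf.getvalue()

    def write(self, path, annotations: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(annotations=annotations) + "\n")

    # ---------------------------------------------------------------- queries
    @property
    def leaf_names(self) -> list[str]:
        """Leaf names in depth-first pre-order (canonical species order)."""
        return [leaf.name for leaf in self.root.leaves()]

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def mrca(self, leaf_names: Iterable[str]) -> TreeNode:
        """Last common ancestor of the given leaves."""
        wanted = set(leaf_names)
        if not wanted:
            raise ValueError("mrca of an empty leaf set is undefined")
        missing = wanted - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        node = self.root
        while True:
            hits = [c for c in node.children if wanted <= _leafset(c)]
            if len(hits) == 1:
                node = hits[0]
            else:
                return node

    def prune_to(self, leaf_names: Iterable[str]) -> "SpeciesTree":
        """Return a copy restricted to the given leaves, with unifurcations
        collapsed (the deeper label wins when both nodes are labelled)."""
        keep = set(leaf_names)
        missing = keep - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        if not keep:
            raise ValueError("cannot prune to an empty leaf set")
        pruned = _prune(self.root, keep)
        assert pruned is not None
        while len(pruned.children) == 1:
            pruned = pruned.children[0]
        pruned.parent = None
        return SpeciesTree(pruned)

    def label_internal(self, prefix: str = "node") -> None:
        """Give unlabeled internal nodes deterministic pre-order labels."""
        for k, node in enumerate(self.preorder()):
            if not node.is_leaf and not node.name:
                node.name = f"{prefix}_{k}"

    def copy(self) -> "SpeciesTree":
        return SpeciesTree.from_newick(self.to_newick())

    def __len__(self) -> int:
        return len(self.leaf_names)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"SpeciesTree({len(self)} leaves)"


def read_tree(path) -> SpeciesTree:
    """Read a rooted species tree from a one-tree Newick file."""
    return SpeciesTree.read(path)


# ---------------------------------------------------------------- helpers

def _first_duplicate(items) -> Optional[str]:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


def _convert(dnode: dendropy.Node) -> TreeNode:
    name = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = TreeNode(name)
    ann = dnode.annotations.get_value("presence")
    if ann is not None:
        node.annotation = float(ann)
    for child in dnode.child_nodes():
        node.add_child(_convert(child))
    return node


def _leafset(node: TreeNode) -> frozenset:
    return frozenset(leaf.name for leaf in node.leaves())


def _prune(node: TreeNode, keep: set) -> Optional[TreeNode]:
    if node.is_leaf:
        if node.name in keep:
            clone = TreeNode(node.name)
            clone.annotation = node.annotation
            return clone
        return None
    kept = [c for c in (_prune(ch, keep) for ch in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    clone = TreeNode(node.name)
    clone.annotation = node.annotation
    for c in kept:
        clone.add_child(c)
    return clone


def _fmt_label(name: str) -> str:
    if _SAFE_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _write_newick(node: TreeNode, buf: io.StringIO, annotations: bool) -> None:
    if node.children:
        buf.write("(")
        for i, child in enumerate(node.children):
            if i:
                buf.write(",")
            _write_newick(child, buf, annotations)
        buf.write(")")
    if node.name:
        buf.write(_fmt_label(node.name))
    if annotations and node.annotation is not None:
        buf.write(f"[&&NHX:presence={node.annotation:.4f}]")
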