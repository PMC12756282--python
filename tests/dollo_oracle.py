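"""Independent brute-force oracle for Dollo parsimony.

Enumerates all rooted binary trees over a labelled leaf set (as nested
tuples) and, for a given presence profile, searches loss-node subsets of
increasing size until one explains the profile under a single gain at the
presence LCA.  Kept deliberately separate from the package's algorithm:
the only shared vocabulary is the Newick string.
"""

from itertools import combinations


def all_rooted_binary_trees(leaves):
    """All rooted binary tree shapes over the given labelled leaves."""
    if len(leaves) == 1:
        return [leaves[0]]
    trees = []
    first, rest = leaves[0], leaves[1:]
    for sub in all_rooted_binary_trees(rest):
        trees.extend(_insert_everywhere(sub, first))
    return trees


def _insert_everywhere(tree, leaf):
    out = [(leaf, tree)]  # new root above the old one
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((new_left, right) for new_left in _insert_everywhere(left, leaf))
        out.extend((left, new_right) for new_right in _insert_everywhere(right, leaf))
    return out


def to_newick(tree):
    if isinstance(tree, tuple):
        return f"({to_newick(tree[0])},{to_newick(tree[1])})"
    return tree


def _collect_nodes(tree, acc):
    """Post-order list of (node, leafset-bitmask) pairs; leaves are ints."""
    if isinstance(tree, tuple):
        left_mask = _collect_nodes(tree[0], acc)
        right_mask = _collect_nodes(tree[1], acc)
        mask = left_mask | right_mask
    else:
        mask = 1 << tree
    acc.append((tree, mask))
    return mask


def min_dollo_losses(tree, presence_mask, n_leaves):
    """Minimum number of loss nodes explaining the profile.

    The gene is gained once at the LCA of the presence leaves; a loss at a
    node wipes its whole subtree.  Searches subsets of candidate nodes in
    increasing cardinality; a subset explains the profile iff the union of
    its leaf sets equals exactly the absent leaves inside the LCA subtree.
    """
    assert presence_mask != 0
    nodes = []
    _collect_nodes(tree, nodes)
    # LCA = smallest-leafset node covering all presences
    covering = [m for _, m in nodes if m & presence_mask == presence_mask]
    lca_mask = min(covering, key=lambda m: bin(m).count("1"))
    target = lca_mask & ~presence_mask  # absent leaves inside the LCA subtree
    if target == 0:
        return 0
    candidates = [m for _, m in nodes if m & lca_mask == m and m & presence_mask == 0]
    for k in range(1, len(candidates) + 1):
        for combo in combinations(candidates, k):
            union = 0
            for m in combo:
                union |= m
            if union == target:
                return k
    raise AssertionError("profile unexplainable — should not happen")
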