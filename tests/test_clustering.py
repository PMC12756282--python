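"""Graph building, module extraction strategies, and their invariants."""

import itertools

import numpy as np
import pytest

from coevoprof import (
    ModuleSet,
    ScoreMatrix,
    build_graph,
    connected_component_modules,
    hierarchical_modules,
    label_propagation_modules,
    make_modules,
    markov_modules,
)


def _sim_matrix(genes, entries, default=0.0):
    n = len(genes)
    m = np.full((n, n), default, dtype=float)
    np.fill_diagonal(m, 0.0)
    idx = {g: i for i, g in enumerate(genes)}
    for (a, b), s in entries.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = s
    return ScoreMatrix(genes, genes, m, metric="test", orientation="similarity")


def test_build_graph_threshold_rule():
    sm = _sim_matrix(["a", "b", "c"], {("a", "b"): 8, ("b", "c"): 6})
    g = build_graph(sm, threshold=7).graph
    assert set(g.edges) == {("a", "b")}


def test_build_graph_distance_orientation():
    genes = ["a", "b", "c"]
    m = np.array([[0, 0.1, 0.5], [0.1, 0, 0.9], [0.5, 0.9, 0]])
    sm = ScoreMatrix(genes, genes, m, metric="jaccard", orientation="distance")
    g = build_graph(sm, threshold=0.2).graph
    assert set(g.edges) == {("a", "b")}


def test_build_graph_excludes_pairs_and_nans():
    sm = _sim_matrix(["a", "b", "c"], {("a", "b"): 10, ("b", "c"): 9})
    sm.scores[0, 2] = sm.scores[2, 0] = np.nan
    gg = build_graph(sm, threshold=1, exclude_pairs={frozenset(("a", "b"))})
    assert set(gg.graph.edges) == {("b", "c")}
    assert gg.excluded_pairs == 1


def test_threshold_monotonicity():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(10)]
    m = rng.random((10, 10))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    sm = ScoreMatrix(genes, genes, m, metric="r", orientation="similarity")
    prev = None
    for thr in (0.2, 0.4, 0.6, 0.8):
        edges = set(build_graph(sm, thr).graph.edges)
        if prev is not None:
            assert edges <= prev
        prev = edges


def test_connected_components_min_size():
    sm = _sim_matrix(
        ["a", "b", "c", "d", "e"],
        {("a", "b"): 1, ("b", "c"): 1, ("d", "e"): 1},
    )
    mods = connected_component_modules(build_graph(sm, 0.5))
    assert len(mods) == 1
    assert mods.modules[0][1] == frozenset(("a", "b", "c"))


def test_connected_components_match_bruteforce_closure():
    """Components equal transitive-closure grouping on random 8-node graphs."""
    genes = list("abcdefgh")
    pairs = list(itertools.combinations(range(8), 2))
    rng = np.random.default_rng(17)
    for _ in range(200):
        m = np.zeros((8, 8))
        for i, j in pairs:
            if rng.random() < 0.2:
                m[i, j] = m[j, i] = 1.0
        sm = ScoreMatrix(genes, genes, m, metric="t", orientation="similarity")
        mods = connected_component_modules(build_graph(sm, 0.5), min_size=1)
        # brute force: iterate merging until fixed point
        groups = [{g} for g in genes]
        changed = True
        while changed:
            changed = False
            for x in range(len(groups)):
                for y in range(x + 1, len(groups)):
                    if any(
                        m[genes.index(a), genes.index(b)] > 0
                        for a in groups[x]
                        for b in groups[y]
                    ):
                        groups[x] |= groups[y]
                        del groups[y]
                        changed = True
                        break
                if changed:
                    break
        expected = {frozenset(g) for g in groups}
        assert {g for _, g in mods.modules} == expected


def test_label_propagation_deterministic_and_finds_cliques():
    sm = _sim_matrix(
        list("abcdef"),
        {("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1,
         ("d", "e"): 1, ("e", "f"): 1, ("d", "f"): 1},
    )
    g = build_graph(sm, 0.5)
    m1 = label_propagation_modules(g, seed=42)
    m2 = label_propagation_modules(g, seed=42)
    assert m1.modules == m2.modules
    assert {gs for _, gs in m1.modules} == {
        frozenset("abc"), frozenset("def")
    }
    assert m1.params["seed"] == 42


def test_label_propagation_drops_singletons():
    sm = _sim_matrix(list("abc"), {("a", "b"): 1})
    mods = label_propagation_modules(build_graph(sm, 0.5), seed=0)
    assert {gs for _, gs in mods.modules} == {frozenset("ab")}


def test_markov_modules_block_diagonal():
    genes = list("abcdef")
    m = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        m[i, j] = m[j, i] = 5.0
    for i, j in [(3, 4), (3, 5), (4, 5)]:
        m[i, j] = m[j, i] = 5.0
    sm = ScoreMatrix(genes, genes, m, metric="t", orientation="similarity")
    mods = markov_modules(sm, inflation=2.0)
    assert {gs for _, gs in mods.modules} == {frozenset("abc"), frozenset("def")}


def test_markov_modules_no_affinity_no_modules():
    genes = list("abcd")
    sm = ScoreMatrix(genes, genes, np.zeros((4, 4)), metric="t",
                     orientation="similarity")
    assert len(markov_modules(sm, inflation=2.0)) == 0


def test_markov_modules_rejects_low_inflation():
    genes = list("ab")
    sm = ScoreMatrix(genes, genes, np.zeros((2, 2)), metric="t",
                     orientation="similarity")
    with pytest.raises(ValueError, match="inflation"):
        markov_modules(sm, inflation=0.5)


def test_hierarchical_identical_pairs():
    genes = ["g1", "g2", "g3", "g4"]
    d = np.array(
        [[0, 0, 0.9, 0.9], [0, 0, 0.9, 0.9], [0.9, 0.9, 0, 0], [0.9, 0.9, 0, 0]],
        dtype=float,
    )
    sm = ScoreMatrix(genes, genes, d, metric="jaccard", orientation="distance")
    mods = hierarchical_modules(sm, mode="n_clusters", value=2)
    assert {gs for _, gs in mods.modules} == {frozenset(("g1", "g2")),
                                              frozenset(("g3", "g4"))}
    zero_cut = hierarchical_modules(sm, mode="cut_distance", value=0.0)
    assert {gs for _, gs in zero_cut.modules} == {frozenset(("g1", "g2")),
                                                  frozenset(("g3", "g4"))}
    singletons = hierarchical_modules(sm, mode="n_clusters", value=4)
    assert all(len(gs) == 1 for _, gs in singletons.modules)
    with pytest.raises(ValueError, match="n_clusters"):
        hierarchical_modules(sm, mode="n_clusters", value=9)


def test_hierarchical_full_dendrogram_encoding():
    genes = ["g1", "g2", "g3"]
    d = np.array([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]])
    sm = ScoreMatrix(genes, genes, d, metric="jaccard", orientation="distance")
    tree = hierarchical_modules(sm, mode="full_dendrogram")
    assert isinstance(tree, list) and len(tree) == 3  # [left, right, height]


def test_modules_are_disjoint_and_ordering_stable():
    with pytest.raises(ValueError, match="disjoint"):
        ModuleSet([("m1", frozenset("ab")), ("m2", frozenset("bc"))], method="x")
    sm = _sim_matrix(list("abcdef"),
                     {("a", "b"): 1, ("e", "f"): 1, ("c", "d"): 1})
    out = connected_component_modules(build_graph(sm, 0.5), min_size=2)
    assert [mid for mid, _ in out.modules] == ["module_1", "module_2", "module_3"]
    assert out.modules[0][1] == frozenset("ab")  # size ties -> smallest member


def test_make_modules_dispatch(small_profiles, quartet_tree):
    from coevoprof import distance_profiles

    sm = distance_profiles(small_profiles, "jaccard")
    mods = make_modules(sm, method="cc", threshold=0.0, min_size=2)
    assert {gs for _, gs in mods.modules} == {frozenset(("g1", "g2"))}
    with pytest.raises(ValueError, match="unknown clustering"):
        make_modules(sm, method="spectral", threshold=0.5)


def test_moduleset_roundtrip(tmp_path):
    mods = ModuleSet(
        [("module_1", frozenset(("a", "b", "c"))), ("module_2", frozenset(("d", "e")))],
        method="cc",
    )
    path = tmp_path / "mods.tsv"
    mods.write(path)
    back = ModuleSet.read(path)
    assert {gs for _, gs in back.modules} == {gs for _, gs in mods.modules}
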