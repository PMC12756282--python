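"""Metric correctness against independent brute-force oracles and the
documented transition-score laws."""

import itertools

import numpy as np
import pytest
from scipy.linalg import svd as scipy_svd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.metrics import mutual_info_score

from coevoprof import (
    ProfileMatrix,
    cotr_score,
    distance_profiles,
    hamming_distance,
    jaccard_distance,
    mutual_information,
    pcs_score,
    pearson_similarity,
    svdphy_distances,
    transition_vectors,
)
from conftest import all_binary_vectors, random_binary_pairs

import pandas as pd


# ------------------------------------------------------------- pair oracles

def _jaccard_oracle(x, y):
    x1 = {i for i, v in enumerate(x) if v == 1}
    y1 = {i for i, v in enumerate(y) if v == 1}
    if not x1 | y1:
        return 0.0
    return 1.0 - len(x1 & y1) / len(x1 | y1)


def _hamming_oracle(x, y):
    return sum(a != b for a, b in zip(x, y)) / len(x)


def _mi_oracle(x, y):
    # sklearn computes MI in nats from the contingency table
    return mutual_info_score(x, y) / np.log(2)


def test_simple_metrics_match_bruteforce_oracles():
    """Jaccard/Hamming/Pearson/MI agree with independent evaluations of
    their defining formulas on 200 seeded random pairs."""
    for x, y in random_binary_pairs(200, 20):
        assert jaccard_distance(x, y) == pytest.approx(_jaccard_oracle(x, y), abs=1e-12)
        assert hamming_distance(x, y) == pytest.approx(_hamming_oracle(x, y), abs=1e-12)
        assert mutual_information(x, y) == pytest.approx(_mi_oracle(x, y), abs=1e-12)
        p = pearson_similarity(x, y)
        if np.isnan(p):
            assert x.std() == 0 or y.std() == 0
        else:
            assert p == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 1, 0, 0), (1, 0, 1, 0), 1 - 1 / 3),
        ((1, 0, 1), (1, 0, 1), 0.0),
        ((0, 0, 0), (0, 0, 0), 0.0),  # empty-union convention
    ],
)
def test_jaccard_examples(x, y, expected):
    assert jaccard_distance(x, y) == pytest.approx(expected)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((1, 1, 0, 0), (1, 0, 1, 0), 0.5),
        ((1, 0, 1), (1, 0, 1), 0.0),
        ((1, 0, 1, 0), (0, 1, 0, 1), 1.0),
    ],
)
def test_hamming_examples(x, y, expected):
    assert hamming_distance(x, y) == pytest.approx(expected)


def test_pearson_examples():
    assert pearson_similarity((1, 0, 1, 0), (1, 0, 1, 0)) == pytest.approx(1.0)
    assert pearson_similarity((1, 0, 1, 0), (0, 1, 0, 1)) == pytest.approx(-1.0)
    assert pearson_similarity((1, 1, 0, 0), (1, 0, 1, 0)) == pytest.approx(0.0)
    assert np.isnan(pearson_similarity((1, 1, 1), (1, 0, 1)))


def test_mutual_information_examples():
    assert mutual_information((1, 1, 0, 0), (1, 1, 0, 0)) == pytest.approx(1.0)
    assert mutual_information((1, 1, 0, 0), (1, 0, 1, 0)) == pytest.approx(0.0)
    assert mutual_information((1, 1, 1, 1), (1, 0, 1, 0)) == pytest.approx(0.0)


def test_length_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        jaccard_distance((1, 0), (1, 0, 1))


def test_discrete_only_metrics_reject_non_binary():
    with pytest.raises(ValueError):
        hamming_distance((0.5, 1), (1, 0))


# -------------------------------------------------------------- transitions

def _transitions_oracle(v):
    """Window-by-window enumeration of the four transition patterns."""
    v = list(v)
    t1 = [1 if v[i:i + 2] == [0, 1] else 0 for i in range(len(v) - 1)]
    t2 = [1 if v[i:i + 2] == [1, 0] else 0 for i in range(len(v) - 1)]
    t3 = [1 if v[i:i + 4] == [0, 0, 1, 1] else 0 for i in range(len(v) - 3)]
    t4 = [1 if v[i:i + 4] == [1, 1, 0, 0] else 0 for i in range(len(v) - 3)]
    return t1, t2, t3, t4


def test_transition_vector_examples():
    tv = transition_vectors([0, 0, 1, 1, 0])
    assert tv.t1.tolist() == [0, 1, 0, 0]
    assert tv.t2.tolist() == [0, 0, 0, 1]
    assert tv.t3.tolist() == [1, 0]
    assert tv.t4.tolist() == [0, 0]
    tv = transition_vectors([1, 1, 0, 0])
    assert tv.t1.tolist() == [0, 0, 0]
    assert tv.t2.tolist() == [0, 1, 0]
    assert tv.t3.tolist() == [0]
    assert tv.t4.tolist() == [1]
    tv = transition_vectors([0, 0, 0])
    assert tv.t1.sum() == tv.t2.sum() == 0 and len(tv.t3) == 0


def test_transition_vectors_match_window_enumeration():
    for n in range(2, 9):
        for v in all_binary_vectors(n):
            tv = transition_vectors(v)
            t1, t2, t3, t4 = _transitions_oracle(v)
            assert tv.t1.tolist() == t1 and tv.t2.tolist() == t2
            assert tv.t3.tolist() == t3 and tv.t4.tolist() == t4
            # a 2-window matches at most one directed pattern
            assert not np.any((tv.t1 == 1) & (tv.t2 == 1))
            # rises and falls of a binary sequence alternate
            assert abs(int(tv.t1.sum()) - int(tv.t2.sum())) <= 1


# ---------------------------------------------------------------------- PCS

def test_pcs_examples():
    tv = transition_vectors([0, 0, 1, 1, 0])
    tz = transition_vectors([0, 0, 0, 0, 0])
    assert pcs_score(tv, tv, w=1.5, p=0.6) == pytest.approx(3.5)
    assert pcs_score(tv, tz, w=1.5, p=0.6) == pytest.approx(-0.6 * (1 + 1 + 1.5))
    assert pcs_score(tz, tz, w=1.5, p=0.6) == 0.0


def test_pcs_identity_law_exhaustive():
    """PCS(X, X) equals the weighted count of X's own transitions."""
    w, p = 1.5, 0.6
    for n in range(4, 9):
        for v in all_binary_vectors(n):
            tv = transition_vectors(v)
            expected = tv.t1.sum() + tv.t2.sum() + w * (tv.t3.sum() + tv.t4.sum())
            assert pcs_score(tv, tv, w=w, p=p) == pytest.approx(expected)


def test_pcs_symmetry_and_penalty_monotonicity():
    w, p = 1.5, 0.6
    for x, y in random_binary_pairs(50, 12, seed=7):
        tx, ty = transition_vectors(x), transition_vectors(y)
        assert pcs_score(tx, ty, w, p) == pytest.approx(pcs_score(ty, tx, w, p))
    # removing one shared transition never increases the score when p > 0
    x = np.array([0, 0, 1, 1, 0, 1, 1, 0])
    y = x.copy()
    full = pcs_score(transition_vectors(x), transition_vectors(y), w, p)
    y2 = y.copy()
    y2[4] = 1  # erases the shared (1,0)/(0,1) pair around position 4
    reduced = pcs_score(transition_vectors(x), transition_vectors(y2), w, p)
    assert reduced < full


def test_pcs_literal_reading_counts_shared_absences():
    tz = transition_vectors([0, 0, 0, 0, 0])
    assert pcs_score(tz, tz, w=1.0, p=0.6, literal=True) == pytest.approx(
        4 + 4 + 2 + 2
    )


# --------------------------------------------------------------------- cotr

def test_cotr_examples():
    tv = transition_vectors([0, 0, 1, 1, 0])
    comp = transition_vectors([1, 1, 0, 0, 1])
    tz = transition_vectors([0, 0, 0, 0, 0])
    score, _ = cotr_score(tv, tv)
    assert score == pytest.approx(1.0)
    score, _ = cotr_score(tv, comp)
    assert score == pytest.approx(-1.0)
    score, _ = cotr_score(tz, tz)
    assert score == 0.0


def test_cotr_bounds_and_extremes_exhaustive():
    """|score| <= 1 over all pairs of length <= 6; +1 iff all transitions
    shared concordantly, -1 iff all opposed."""
    for n in range(4, 7):
        vectors = all_binary_vectors(n)
        for x in vectors:
            for y in vectors:
                tx, ty = transition_vectors(x), transition_vectors(y)
                score, pval = cotr_score(tx, ty)
                assert -1.0 <= score <= 1.0
                assert 0.0 <= pval <= 1.0
        for x in vectors:
            tx = transition_vectors(x)
            if tx.total > 0:
                assert cotr_score(tx, tx)[0] == pytest.approx(1.0)
                tc = transition_vectors(1 - x)
                assert cotr_score(tx, tc)[0] == pytest.approx(-1.0)


def test_mi_nonnegative_and_symmetric_exhaustive():
    for n in range(2, 9):
        vectors = all_binary_vectors(n)
        for x in vectors[:: max(1, len(vectors) // 16)]:
            for y in vectors[:: max(1, len(vectors) // 16)]:
                mi_xy = mutual_information(x, y)
                assert mi_xy >= 0
                assert mi_xy == pytest.approx(mutual_information(y, x), abs=1e-12)


# ------------------------------------------------------------------ SVD-Phy

def _svd_oracle(values, truncation):
    u, s, vt = scipy_svd(values.astype(float), full_matrices=False)
    c = max(1, round(truncation * values.shape[1]))
    rank = max(1, int(np.sum(s > s[0] * 1e-12)))
    return squareform(pdist(u[:, : min(c, u.shape[1], rank)]))


def test_svdphy_duplicated_rows_are_at_zero_distance(rng):
    values = rng.integers(0, 2, size=(6, 10))
    values[3] = values[0]
    pm = ProfileMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(6)],
                                    columns=[f"s{j}" for j in range(10)]))
    for truncation in (0.1, 0.3, 0.5, 1.0):
        d = svdphy_distances(pm, truncation=truncation)
        assert d.scores[0, 3] == pytest.approx(0.0, abs=1e-9)


def test_svdphy_matches_independent_decomposition(rng):
    values = rng.integers(0, 2, size=(8, 12))
    pm = ProfileMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(8)],
                                    columns=[f"s{j}" for j in range(12)]))
    for truncation in (0.5, 1.0):
        d = svdphy_distances(pm, truncation=truncation)
        # distances are invariant to the sign ambiguity of singular vectors
        # only at truncation=1.0; at 0.5 compare against the same column cut
        oracle = _svd_oracle(values, truncation)
        if truncation == 1.0:
            assert np.allclose(d.scores, oracle, atol=1e-9)
        else:
            assert d.scores == pytest.approx(oracle, abs=1e-6)


def test_svdphy_is_pseudometric(rng):
    values = rng.integers(0, 2, size=(7, 15))
    pm = ProfileMatrix(pd.DataFrame(values, index=[f"g{i}" for i in range(7)],
                                    columns=[f"s{j}" for j in range(15)]))
    d = svdphy_distances(pm, truncation=0.4).scores
    assert np.all(d >= -1e-12)
    assert np.allclose(d, d.T, atol=1e-9)
    n = d.shape[0]
    for i, j, k in itertools.permutations(range(n), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_svdphy_rejects_bad_truncation(small_profiles):
    with pytest.raises(ValueError, match="truncation"):
        svdphy_distances(small_profiles, truncation=0.0)


# -------------------------------------------------------- distance_profiles

def test_distance_profiles_matches_single_pair_ops(small_profiles, quartet_tree):
    """Every matrix entry equals the corresponding pair operation applied
    to the same (tree-ordered, for tree metrics) profile rows."""
    ordered = small_profiles  # columns A,B,C,D already in tree pre-order
    rows = {g: ordered.profile(g).to_numpy() for g in ordered.gene_ids}
    cases = {
        "jaccard": lambda a, b: jaccard_distance(rows[a], rows[b]),
        "hamming": lambda a, b: hamming_distance(rows[a], rows[b]),
        "mi": lambda a, b: mutual_information(rows[a], rows[b]),
        "pcs": lambda a, b: pcs_score(
            transition_vectors(rows[a]), transition_vectors(rows[b])
        ),
        "cotr": lambda a, b: cotr_score(
            transition_vectors(rows[a]), transition_vectors(rows[b])
        )[0],
    }
    for method, oracle in cases.items():
        sm = distance_profiles(small_profiles, method, tree=quartet_tree)
        for i, a in enumerate(sm.row_ids):
            for j, b in enumerate(sm.col_ids):
                if method in ("jaccard", "hamming") and i == j:
                    continue
                assert sm.scores[i, j] == pytest.approx(oracle(a, b), abs=1e-12), (
                    method, a, b,
                )


def test_distance_profiles_shapes_and_orientation(small_profiles, quartet_tree):
    sm = distance_profiles(small_profiles, "jaccard")
    assert sm.scores.shape == (5, 5)
    assert sm.orientation == "distance"
    assert np.allclose(np.diag(sm.scores), 0)
    assert np.allclose(sm.scores, sm.scores.T, atol=1e-9)
    row = distance_profiles(small_profiles, "pcs", tree=quartet_tree, targets=["g1"])
    assert row.scores.shape == (1, 5)
    assert row.row_ids == ["g1"]


def test_distance_profiles_errors(small_profiles):
    with pytest.raises(ValueError, match="tree"):
        distance_profiles(small_profiles, "pcs")
    with pytest.raises(ValueError, match="unknown method"):
        distance_profiles(small_profiles, "cosine")
    cont = ProfileMatrix(small_profiles.data.astype(float) * 0.7, mode="continuous")
    with pytest.raises(ValueError, match="discrete"):
        distance_profiles(cont, "jaccard")


def test_cotr_fills_pvalues(small_profiles, quartet_tree):
    sm = distance_profiles(small_profiles, "cotr", tree=quartet_tree)
    assert sm.pvalues is not None
    assert sm.pvalues.shape == sm.scores.shape
    assert np.all((sm.pvalues >= 0) & (sm.pvalues <= 1))
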