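"""Profile similarity and distance measures.

Seven measures are implemented, in two families:

* vector comparisons on the raw profiles — Jaccard distance, Hamming
  distance, Pearson correlation, mutual information, and SVD-based
  Euclidean distance on the left singular vectors ("SVD" metric);
* transition-based comparisons on tree-ordered profiles — the phylogenetic
  co-occurrence score (PCS) and the co-transition score.

The transition-based scores first convert each tree-ordered binary profile
into indicator vectors of presence/absence changes between adjacent
species: T1 marks windows (0,1), T2 marks (1,0), and T3/T4 mark the
two-species-supported variants (0,0,1,1) and (1,1,0,0).  Adjacent columns
of a tree-ordered profile are phylogenetically close, so a shared
transition is evidence of a shared evolutionary event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom

from .io import CONTINUOUS, ProfileMatrix, tree_order
from .tree import SpeciesTree

__all__ = [
    "TransitionVectors",
    "ScoreMatrix",
    "jaccard_distance",
    "hamming_distance",
    "pearson_similarity",
    "mutual_information",
    "transition_vectors",
    "pcs_score",
    "cotr_score",
    "svdphy_distances",
    "distance_profiles",
    "METRICS",
    "DEFAULT_TRUNCATION",
    "DEFAULT_CONFIDENCE",
    "DEFAULT_PENALTY",
]

# Defaults follow the original descriptions of each method.
DEFAULT_TRUNCATION = 0.3
#: preset used in the global benchmarks of the SVD metric
BENCHMARK_TRUNCATION = 0.5
DEFAULT_CONFIDENCE = 1.5
DEFAULT_PENALTY = 0.6

#: metric name -> (orientation, accepts continuous input, needs species tree)
METRICS: dict[str, tuple[str, bool, bool]] = {
    "jaccard": ("distance", False, False),
    "hamming": ("distance", False, False),
    "pearson": ("similarity", True, False),
    "mi": ("similarity", False, False),
    "svdphy": ("distance", True, False),
    "pcs": ("similarity", False, True),
    "cotr": ("similarity", False, True),
}


@dataclass
class TransitionVectors:
    """Sliding-window transition indicators of one tree-ordered profile.

    ``t1``/``t2`` have length n-1 (2-windows), ``t3``/``t4`` length n-3
    (4-windows); ``n`` is the profile length.  Windows are evaluated
    independently per pattern.
    """

    t1: np.ndarray
    t2: np.ndarray
    t3: np.ndarray
    t4: np.ndarray
    n: int

    @property
    def total(self) -> int:
        """Total number of single transitions (T1 + T2)."""
        return int(self.t1.sum() + self.t2.sum())


@dataclass
class ScoreMatrix:
    """All-vs-all or targets-vs-all metric results.

    ``orientation`` records whether larger scores mean more similar
    ("similarity") or less similar ("distance"); downstream thresholding,
    ranking and clustering are orientation-aware.  ``pvalues`` is filled by
    the co-transition metric only.  NaN marks undefined cells (e.g. Pearson
    against a constant profile).
    """

    row_ids: list[str]
    col_ids: list[str]
    scores: np.ndarray
    metric: str
    orientation: str
    params: dict = field(default_factory=dict)
    pvalues: Optional[np.ndarray] = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if self.orientation not in ("similarity", "distance"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.row_ids, columns=self.col_ids)

    def write(self, path, delimiter: str = "tab") -> None:
        sep = "\t" if delimiter in ("tab", "\t") else ","
        self.to_dataframe().to_csv(path, sep=sep)
        if self.pvalues is not None:
            pd.DataFrame(self.pvalues, index=self.row_ids, columns=self.col_ids).to_csv(
                str(path) + ".pvalues", sep=sep
            )


# ---------------------------------------------------------------- pair ops

def _check_pair(x, y, discrete: bool = True) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if discrete and not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("metric requires discrete (0/1) profiles")
    return x, y


def jaccard_distance(x: Sequence, y: Sequence) -> float:
    """1 - |X1 n Y1| / |X1 u Y1| over the presence sets; 0 when both
    profiles are all-absent (degenerate profiles treated as identical)."""
    x, y = _check_pair(x, y)
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(x, y).sum()
    return float(1.0 - inter / union)


def hamming_distance(x: Sequence, y: Sequence) -> float:
    """Fraction of species where the two profiles disagree."""
    x, y = _check_pair(x, y)
    return float(np.mean(x != y))


def pearson_similarity(x: Sequence, y: Sequence) -> float:
    """Sample Pearson correlation; NaN when either profile has zero
    variance (undefined, excluded from downstream ranking)."""
    x, y = _check_pair(x, y, discrete=False)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Mutual information (bits) of the joint presence/absence counts,
    with the convention 0 * log 0 = 0."""
    x, y = _check_pair(x, y)
    n = len(x)
    mi = 0.0
    for i in (0, 1):
        for j in (0, 1):
            nij = np.sum((x == i) & (y == j))
            if nij == 0:
                continue
            ni = np.sum(x == i)
            nj = np.sum(y == j)
            mi += (nij / n) * np.log2(nij * n / (ni * nj))
    return float(max(mi, 0.0))


def transition_vectors(v: Sequence) -> TransitionVectors:
    """Build the T1..T4 transition indicator vectors of one tree-ordered
    binary profile.  Profiles shorter than 4 get empty T3/T4."""
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError("transition vectors require a binary profile")
    v = v.astype(np.int8)
    n = len(v)
    if n >= 2:
        t1 = ((v[:-1] == 0) & (v[1:] == 1)).astype(np.int8)
        t2 = ((v[:-1] == 1) & (v[1:] == 0)).astype(np.int8)
    else:
        t1 = t2 = np.zeros(0, dtype=np.int8)
    if n >= 4:
        t3 = ((v[:-3] == 0) & (v[1:-2] == 0) & (v[2:-1] == 1) & (v[3:] == 1)).astype(np.int8)
        t4 = ((v[:-3] == 1) & (v[1:-2] == 1) & (v[2:-1] == 0) & (v[3:] == 0)).astype(np.int8)
    else:
        t3 = t4 = np.zeros(0, dtype=np.int8)
    return TransitionVectors(t1, t2, t3, t4, n)


def pcs_score(
    tx: TransitionVectors,
    ty: TransitionVectors,
    w: float = DEFAULT_CONFIDENCE,
    p: float = DEFAULT_PENALTY,
    literal: bool = False,
) -> float:
    """Phylogenetic co-occurrence score between two transition decompositions.

    With m_k the number of window positions where both profiles show the
    pattern k and u_k the positions where exactly one does::

        PCS = m1 + m2 + w*(m3 + m4) - p*(u1 + u2 + w*(u3 + u4))

    ``w`` weights the two-species-supported patterns T3/T4, ``p`` penalises
    unshared transitions.  A shared transition is counted only where both
    indicator vectors equal 1, so the score grows with the number of shared
    evolutionary transitions rather than with profile length.
    ``literal=True`` restores the equality-indicator reading in which
    windows where both profiles lack the pattern also count as matches.
    """
    if tx.n != ty.n:
        raise ValueError(f"profile length mismatch: {tx.n} vs {ty.n}")
    score = 0.0
    for a, b, wk in (
        (tx.t1, ty.t1, 1.0),
        (tx.t2, ty.t2, 1.0),
        (tx.t3, ty.t3, w),
        (tx.t4, ty.t4, w),
    ):
        m = int(np.sum((a == 1) & (b == 1)))
        u = int(np.sum(a != b))
        if literal:
            m = len(a) - u
        score += wk * m - p * wk * u
    return float(score)


def cotr_score(tx: TransitionVectors, ty: TransitionVectors) -> tuple[float, float]:
    """Co-transition score and its p-value.

    At each 2-window a profile transitions up (T1), down (T2) or not at
    all.  With c the windows where both profiles transition in the same
    direction, d the windows where they transition in opposite directions,
    and Tx, Ty the transition totals::

        score = (c - d) / (|Tx - Ty| + |c - d|)

    which lies in [-1, 1]; 0/0 is defined as 0 (no transitions to compare).
    The p-value is the hypergeometric upper tail of observing >= c
    concordant windows given Tx and Ty transitions placed among the n - 1
    windows — the probability that two unrelated profiles with these many
    transitions would co-occur at least this often by chance.
    """
    if tx.n != ty.n:
        raise ValueError(f"profile length mismatch: {tx.n} vs {ty.n}")
    dx = tx.t1.astype(np.int8) - tx.t2.astype(np.int8)
    dy = ty.t1.astype(np.int8) - ty.t2.astype(np.int8)
    c = int(np.sum((dx != 0) & (dx == dy)))
    d = int(np.sum((dx != 0) & (dy != 0) & (dx != dy)))
    t_x, t_y = tx.total, ty.total
    denom = abs(t_x - t_y) + abs(c - d)
    score = 0.0 if denom == 0 else (c - d) / denom
    windows = max(tx.n - 1, 1)
    pvalue = float(hypergeom.sf(c - 1, windows, min(t_x, windows), min(t_y, windows)))
    return float(score), pvalue


# ------------------------------------------------------------- matrix ops

def svdphy_distances(
    profiles: ProfileMatrix, truncation: float = DEFAULT_TRUNCATION
) -> ScoreMatrix:
    """SVD-based profile distance.

    The profile matrix M is factored M = U S Vt with the economy SVD; the
    first C = max(1, round(truncation * n_species)) columns of U are kept
    and pairwise Euclidean distances between the retained rows are
    returned.  Truncation discards low-variance directions, down-weighting
    redundant signal from clusters of closely related species.
    """
    if not (0 < truncation <= 1):
        raise ValueError(f"truncation must be in (0, 1], got {truncation}")
    if profiles.n_genes < 2:
        raise ValueError("need at least 2 genes")
    m = profiles.values.astype(float)
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    c = max(1, round(truncation * profiles.n_species))
    # never keep null-space columns: they are arbitrary up to rotation and
    # would put identical profiles at nonzero distance
    rank = max(1, int(np.sum(s > (s[0] * 1e-12 if s.size and s[0] > 0 else 0))))
    c = min(c, u.shape[1], rank)
    kept = u[:, :c]
    dists = cdist(kept, kept, metric="euclidean")
    np.fill_diagonal(dists, 0.0)
    return ScoreMatrix(
        profiles.gene_ids,
        profiles.gene_ids,
        dists,
        metric="svdphy",
        orientation="distance",
        params={"truncation": truncation, "columns_kept": c},
    )


def _transition_matrices(values: np.ndarray):
    """Stack per-gene transition vectors into matrices (vectorised T1..T4)."""
    v = values.astype(np.int8)
    t1 = ((v[:, :-1] == 0) & (v[:, 1:] == 1)).astype(float)
    t2 = ((v[:, :-1] == 1) & (v[:, 1:] == 0)).astype(float)
    if v.shape[1] >= 4:
        t3 = ((v[:, :-3] == 0) & (v[:, 1:-2] == 0) & (v[:, 2:-1] == 1) & (v[:, 3:] == 1)).astype(float)
        t4 = ((v[:, :-3] == 1) & (v[:, 1:-2] == 1) & (v[:, 2:-1] == 0) & (v[:, 3:] == 0)).astype(float)
    else:
        t3 = t4 = np.zeros((v.shape[0], 0))
    return t1, t2, t3, t4


def _pairwise_pcs(xv, yv, w, p, literal):
    score = np.zeros((xv.shape[0], yv.shape[0]))
    xt = _transition_matrices(xv)
    yt = _transition_matrices(yv)
    for a, b, wk in ((xt[0], yt[0], 1.0), (xt[1], yt[1], 1.0), (xt[2], yt[2], w), (xt[3], yt[3], w)):
        m = a @ b.T
        u = a.sum(1)[:, None] + b.sum(1)[None, :] - 2 * m
        if literal:
            m = a.shape[1] - u
        score += wk * m - p * wk * u
    return score


def _pairwise_cotr(xv, yv):
    xt = _transition_matrices(xv)
    yt = _transition_matrices(yv)
    dx = xt[0] - xt[1]
    dy = yt[0] - yt[1]
    up_x, dn_x = (dx > 0).astype(float), (dx < 0).astype(float)
    up_y, dn_y = (dy > 0).astype(float), (dy < 0).astype(float)
    c = up_x @ up_y.T + dn_x @ dn_y.T
    d = up_x @ dn_y.T + dn_x @ up_y.T
    t_x = np.abs(dx).sum(1)
    t_y = np.abs(dy).sum(1)
    denom = np.abs(t_x[:, None] - t_y[None, :]) + np.abs(c - d)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom == 0, 0.0, (c - d) / np.where(denom == 0, 1.0, denom))
    windows = max(xv.shape[1] - 1, 1)
    pvals = hypergeom.sf(
        (c - 1).astype(int),
        windows,
        np.minimum(t_x, windows).astype(int)[:, None],
        np.minimum(t_y, windows).astype(int)[None, :],
    )
    return score, pvals


def _pairwise_mi(xv, yv):
    x = xv.astype(float)
    y = yv.astype(float)
    n = x.shape[1]
    n11 = x @ y.T
    n10 = x @ (1 - y).T
    n01 = (1 - x) @ y.T
    n00 = (1 - x) @ (1 - y).T
    rx1 = x.sum(1)[:, None]
    ry1 = y.sum(1)[None, :]
    mi = np.zeros_like(n11)
    for nij, ni, nj in (
        (n11, rx1, ry1),
        (n10, rx1, n - ry1),
        (n01, n - rx1, ry1),
        (n00, n - rx1, n - ry1),
    ):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = (nij / n) * np.log2(nij * n / (ni * nj))
        mi += np.where(nij == 0, 0.0, term)
    return np.maximum(mi, 0.0)


def _pairwise_pearson(xv, yv):
    x = xv.astype(float) - xv.mean(1, keepdims=True)
    y = yv.astype(float) - yv.mean(1, keepdims=True)
    nx = np.sqrt((x * x).sum(1))
    ny = np.sqrt((y * y).sum(1))
    denom = nx[:, None] * ny[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((x @ y.T) / denom, -1.0, 1.0)
    r[denom == 0] = np.nan
    return r


def _pairwise_jaccard(xv, yv):
    x = xv.astype(float)
    y = yv.astype(float)
    inter = x @ y.T
    union = x.sum(1)[:, None] + y.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    return np.where(union == 0, 0.0, d)


def distance_profiles(
    profiles: ProfileMatrix,
    method: str,
    tree: Optional[SpeciesTree] = None,
    targets: Optional[Sequence[str]] = None,
    **params,
) -> ScoreMatrix:
    """Compute a metric over all gene pairs (all-against-all) or between a
    target gene set and all genes (some-against-all).

    Parameters
    ----------
    method:
        One of ``jaccard``, ``hamming``, ``pearson``, ``mi``, ``svdphy``,
        ``pcs``, ``cotr``.
    tree:
        Species tree; required for the tree-aware metrics (pcs, cotr),
        which operate on tree-ordered profiles.
    targets:
        Optional subset of gene ids; the result is a targets x all matrix.
    params:
        ``truncation`` for svdphy; ``confidence`` (w), ``penalty`` (p) and
        ``literal`` for pcs.
    """
    if method not in METRICS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METRICS)}")
    orientation, allows_continuous, needs_tree = METRICS[method]
    if profiles.mode == CONTINUOUS and not allows_continuous:
        raise ValueError(
            f"method {method!r} requires discrete profiles; "
            "binarize(threshold) converts continuous ones"
        )
    if needs_tree:
        if tree is None:
            raise ValueError(f"method {method!r} requires a species tree")
        profiles = tree_order(profiles, tree)

    genes = profiles.gene_ids
    if targets is not None:
        targets = list(targets)
        missing = sorted(set(targets) - set(genes))
        if missing:
            raise ValueError(f"target genes not in profiles: {missing}")
    values = profiles.values

    if method == "svdphy":
        truncation = params.get("truncation", DEFAULT_TRUNCATION)
        full = svdphy_distances(profiles, truncation=truncation)
        if targets is None:
            return full
        idx = [genes.index(t) for t in targets]
        return ScoreMatrix(
            targets, genes, full.scores[idx, :], metric="svdphy",
            orientation="distance", params=full.params,
        )

    xv = values if targets is None else values[[genes.index(t) for t in targets]]
    row_ids = genes if targets is None else targets
    pvalues = None
    used: dict = {}

    if method == "jaccard":
        scores = _pairwise_jaccard(xv, values)
    elif method == "hamming":
        scores = cdist(xv.astype(float), values.astype(float), metric="hamming")
    elif method == "pearson":
        scores = _pairwise_pearson(xv, values)
    elif method == "mi":
        scores = _pairwise_mi(xv, values)
    elif method == "pcs":
        w = params.get("confidence", DEFAULT_CONFIDENCE)
        p = params.get("penalty", DEFAULT_PENALTY)
        literal = params.get("literal", False)
        used = {"confidence": w, "penalty": p, "literal": literal}
        scores = _pairwise_pcs(xv, values, w, p, literal)
    elif method == "cotr":
        scores, pvalues = _pairwise_cotr(xv, values)
    else:  # pragma: no cover
        raise AssertionError(method)

    if targets is None and orientation == "distance":
        np.fill_diagonal(scores, 0.0)
    return ScoreMatrix(
        row_ids, genes, scores, metric=method, orientation=orientation,
        params=used, pvalues=pvalues,
    )
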