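"""Pair-ranking benchmark of profile metrics.

All gene pairs are ranked best-first by a metric; against a list of known
positive pairs (e.g. genes sharing a pathway) the harness computes, at
every rank, the cumulative number of positives and the precision, plus a
trapezoidal area under the (cumulative positives, precision) curve.  A
one-sided Mann-Whitney test compares the Dollo parsimony scores of
positive versus negative pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import auc as sk_auc

from .metrics import ScoreMatrix

__all__ = [
    "BenchmarkCurve",
    "rank_pairs",
    "precision_curve",
    "parsimony_discrimination",
    "pair_parsimony",
]


@dataclass
class BenchmarkCurve:
    """Precision-vs-cumulative-positives curve over a ranked pair list."""

    table: pd.DataFrame  # rank, gene_a, gene_b, score, is_positive, cum_positives, precision
    auc: float
    max_pairs: int
    n_positive_pairs: int

    def write(self, csv_path, summary_path=None) -> None:
        self.table.to_csv(csv_path, index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(
                    {
                        "auc": self.auc,
                        "max_pairs": self.max_pairs,
                        "ranked_pairs": int(len(self.table)),
                        "positives_found": int(self.table["cum_positives"].iloc[-1]),
                        "positives_known": self.n_positive_pairs,
                    },
                    fh,
                    indent=2,
                )


def rank_pairs(
    scores: ScoreMatrix, exclude_pairs: Optional[set] = None
) -> list[tuple[str, str, float]]:
    """Order the upper-triangle gene pairs best-first.

    Similarities sort descending, distances ascending; undefined (NaN)
    scores and excluded pairs are dropped; ties break by lexicographic pair
    id so the ranking is deterministic.
    """
    if not scores.is_square:
        raise ValueError("rank_pairs requires a square score matrix")
    genes = scores.row_ids
    mat = scores.scores
    exclude_pairs = exclude_pairs or set()
    sign = -1.0 if scores.orientation == "similarity" else 1.0
    items = []
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            s = mat[i, j]
            if not np.isfinite(s):
                continue
            a, b = sorted((genes[i], genes[j]))
            if frozenset((a, b)) in exclude_pairs:
                continue
            items.append((sign * s, a, b, float(s)))
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    return [(a, b, s) for _, a, b, s in items]


def precision_curve(
    ranked: Sequence[tuple], positives: Iterable[frozenset], max_pairs: int = 10_000
) -> BenchmarkCurve:
    """Cumulative positives and precision over the first ``max_pairs``
    ranked pairs, with the trapezoidal AUC over x = cumulative positives,
    y = precision (duplicate x values contribute zero width)."""
    if max_pairs < 1:
        raise ValueError("max_pairs must be >= 1")
    ranked = list(ranked)[: int(max_pairs)]
    if not ranked:
        raise ValueError("empty ranked pair list")
    pos = {frozenset(p) for p in positives}
    rows = []
    cum = 0
    for r, item in enumerate(ranked, start=1):
        a, b = item[0], item[1]
        score = item[2] if len(item) > 2 else float("nan")
        hit = frozenset((a, b)) in pos
        cum += int(hit)
        rows.append((r, a, b, score, int(hit), cum, cum / r))
    table = pd.DataFrame(
        rows,
        columns=["rank", "gene_a", "gene_b", "score", "is_positive",
                 "cum_positives", "precision"],
    )
    x = table["cum_positives"].to_numpy(dtype=float)
    y = table["precision"].to_numpy(dtype=float)
    if len(x) > 1 and x[-1] > x[0]:
        curve_auc = float(sk_auc(x, y))
    else:
        curve_auc = 0.0
    return BenchmarkCurve(table, curve_auc, int(max_pairs), len(pos))


def pair_parsimony(
    pairs: Iterable[frozenset], gene_scores: dict[str, float], mode: str = "min"
) -> list[float]:
    """Reduce each gene pair to a single parsimony score (the minimum of
    the two genes' scores by default; ``mode="max"`` for exploration)."""
    reducer = min if mode == "min" else max
    out = []
    for pair in pairs:
        a, b = tuple(pair)
        if a in gene_scores and b in gene_scores:
            out.append(reducer(gene_scores[a], gene_scores[b]))
    return out


def parsimony_discrimination(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of H1: positive-pair scores are
    stochastically greater than negative-pair scores.

    Small samples (both sides < 20) are evaluated against the exact
    conditional distribution of the rank sum given the observed (possibly
    tied) values, computed by dynamic programming over all group
    relabelings; larger samples use the tie-corrected normal approximation.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    u = float(np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :]))
    if pos.size < 20 and neg.size < 20:
        p = _exact_mwu_p(pos, neg, u)
    else:
        _, p = mannwhitneyu(pos, neg, alternative="greater", method="asymptotic")
    return u, float(p)


def _exact_mwu_p(pos: np.ndarray, neg: np.ndarray, u_obs: float) -> float:
    """Exact one-sided p-value P(U >= u_obs) over all C(n1+n2, n1) group
    assignments of the pooled values (ties via midranks)."""
    from scipy.stats import rankdata

    combined = np.concatenate([pos, neg])
    n1, n = len(pos), len(combined)
    # doubled midranks are integers even with ties
    r2 = np.round(2 * rankdata(combined)).astype(int)
    max_sum = int(r2.sum())
    # ways[j][s] = number of j-subsets of the doubled ranks summing to s
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for rank in r2:
        for j in range(n1, 0, -1):
            ways[j, rank:] += ways[j - 1, : max_sum + 1 - rank]
    # U = R1 - n1(n1+1)/2, so 2*U >= 2*u_obs  <=>  2*R1 >= 2*u_obs + n1(n1+1)
    threshold = int(math.ceil(2 * u_obs + n1 * (n1 + 1) - 1e-9))
    tail = ways[n1, threshold:].sum()
    total = math.comb(n, n1)
    return float(tail / total)
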