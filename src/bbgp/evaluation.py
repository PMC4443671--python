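"""Ranking evaluation: precision, recall, PR curve and average precision.

For a strict best-first ranking of N items of which a known subset is truly
positive ("selected"),

    pre(k) = TP(k) / k,    rec(k) = TP(k) / n_pos,

and average precision is the mean of pre(k) over the ranks k at which a
positive appears:

    AP = sum_k pre(k) * 1_pos(k) / n_pos.

A random ranking has expected AP approximately equal to the positive
fraction n_pos / N, which serves as the line of no discrimination.

Ties must be resolved by the ranker before evaluation; these functions
assume a strict order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "precision_recall_at_k",
    "average_precision",
    "pr_curve",
    "random_baseline_ap",
]


def _hits(ranked_ids, positives) -> np.ndarray:
    ranked = list(ranked_ids)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranking contains duplicate ids")
    pos = set(positives)
    if not pos <= set(ranked):
        raise ValueError("positives must be a subset of the ranked items")
    return np.fromiter((i in pos for i in ranked), dtype=bool, count=len(ranked))


def precision_recall_at_k(ranked_ids, positives, k: int) -> tuple[float, float]:
    """Precision and recall among the k top-ranked items."""
    hits = _hits(ranked_ids, positives)
    if not 1 <= k <= hits.size:
        raise ValueError(f"k must be in [1, {hits.size}], got {k}")
    n_pos = int(hits.sum())
    if n_pos == 0:
        raise ValueError("recall undefined: no positive items")
    tp = int(hits[:k].sum())
    return tp / k, tp / n_pos


def average_precision(ranked_ids, positives) -> float:
    """Mean precision at the ranks of the true positives."""
    hits = _hits(ranked_ids, positives)
    n_pos = int(hits.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined: no positive items")
    k = np.arange(1, hits.size + 1)
    prec = np.cumsum(hits) / k
    return float(prec[hits].sum() / n_pos)


def pr_curve(ranked_ids, positives) -> pd.DataFrame:
    """Precision and recall at every rank, as a tidy table."""
    hits = _hits(ranked_ids, positives)
    n_pos = int(hits.sum())
    if n_pos == 0:
        raise ValueError("PR curve undefined: no positive items")
    k = np.arange(1, hits.size + 1)
    tp = np.cumsum(hits)
    return pd.DataFrame(
        dict(k=k, precision=tp / k, recall=tp / n_pos, is_positive=hits)
    )


def random_baseline_ap(n_pos: int, n_total: int) -> float:
    """Expected AP of a random ranking: the positive fraction n_pos/N."""
    if not 0 < n_pos <= n_total:
        raise ValueError("need 0 < n_pos <= n_total")
    return n_pos / n_total
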