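"""Preranked gene-set enrichment of the final candidate rankings.

The enrichment score (ES) is the maximum deviation of the weighted
Kolmogorov–Smirnov running sum over the ranked list: genes in the set add
|score|^w (normalized over the set's in-list scores), genes outside
subtract 1/(N − N_hit). Sets concentrated at the top of the ranking yield
positive ES. Significance comes from gene-label permutation (random sets of
the same size) with the add-one convention; NES divides ES by the mean
|null ES| of the same sign, and BH adjustment runs across the retained
sets. Counting, across diseases, how many rankings a set is significantly
enriched in summarizes cross-disease relevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = ["GseaResult", "preranked_gsea", "count_significant_diseases"]


@dataclass
class GseaResult:
    """Enrichment of one gene set in one ranked list."""

    set_name: str
    enrichment_score: float
    normalized_enrichment_score: float
    pvalue: float
    qvalue: float
    set_size: int


def _enrichment_scores(hit_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """ES for each row of boolean ``hit_matrix`` over the ranked list.

    ``weights`` = |score|^w per ranked position. Vectorized over sets.
    """
    n = weights.size
    hit_w = hit_matrix * weights  # (n_sets, n)
    hit_tot = hit_w.sum(axis=1, keepdims=True)
    # A set whose in-list scores are all zero contributes uniformly.
    safe = np.where(hit_tot > 0, hit_tot, 1.0)
    p_hit = np.where(hit_tot > 0, hit_w / safe,
                     hit_matrix / np.maximum(hit_matrix.sum(axis=1, keepdims=True), 1))
    n_hits = hit_matrix.sum(axis=1, keepdims=True)
    p_miss = (~hit_matrix) / np.maximum(n - n_hits, 1)
    running = np.cumsum(p_hit - p_miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def preranked_gsea(ranking: pd.Series | Sequence[tuple[str, float]],
                   gene_sets: Mapping[str, Sequence[str]],
                   max_size: int = 2000,
                   min_size: int = 2,
                   n_permutations: int = 1000,
                   weight_exponent: float = 1.0,
                   rng_seed: int = 0) -> list[GseaResult]:
    """Weighted-KS preranked GSEA with gene-label permutation nulls.

    ``ranking`` maps gene → score (any order; sorted descending here), with
    known disease genes already excluded upstream. Sets are intersected
    with the ranked universe; sets larger than ``max_size`` are dropped and
    sets with fewer than ``min_size`` in-list genes skipped with a note.
    """
    if isinstance(ranking, pd.Series):
        series = ranking.astype(float)
    else:
        series = pd.Series({g: float(s) for g, s in ranking})
    series = series.iloc[np.lexsort((series.index.to_numpy(), -series.to_numpy()))]
    genes = series.index.to_numpy()
    scores = series.to_numpy()
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}
    weights = np.abs(scores) ** weight_exponent

    names, hit_rows, sizes = [], [], []
    for name in sorted(gene_sets):
        members = {g for g in gene_sets[name] if g in gene_pos}
        if len(gene_sets[name]) > max_size:
            logger.info("dropping set %s (size %d > max_size)", name, len(gene_sets[name]))
            continue
        if len(members) < min_size:
            logger.info("skipping set %s (only %d gene(s) in ranking)", name, len(members))
            continue
        row = np.zeros(n, dtype=bool)
        row[[gene_pos[g] for g in members]] = True
        names.append(name)
        hit_rows.append(row)
        sizes.append(len(members))
    if not names:
        return []
    hits = np.vstack(hit_rows)
    es = _enrichment_scores(hits, weights)

    rng = np.random.default_rng(rng_seed)
    unique_sizes = sorted(set(sizes))
    null_by_size: dict[int, np.ndarray] = {}
    for size in unique_sizes:
        null_hits = np.zeros((n_permutations, n), dtype=bool)
        for b in range(n_permutations):
            null_hits[b, rng.choice(n, size=size, replace=False)] = True
        null_by_size[size] = _enrichment_scores(null_hits, weights)

    results: list[GseaResult] = []
    pvals = []
    for name, e, size in zip(names, es, sizes):
        null = null_by_size[size]
        same_sign = null[null >= 0] if e >= 0 else null[null < 0]
        if same_sign.size == 0:
            p, nes = 1.0, 0.0
        else:
            extreme = (same_sign >= e).sum() if e >= 0 else (same_sign <= e).sum()
            p = (1.0 + extreme) / (same_sign.size + 1.0)
            denom = np.abs(same_sign).mean()
            nes = float(e / denom) if denom > 0 else 0.0
        pvals.append(p)
        results.append(GseaResult(name, float(e), nes, float(p), np.nan, size))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for res, q in zip(results, qvals):
        res.qvalue = float(q)
    return results


def count_significant_diseases(results_per_disease: Mapping[str, Sequence[GseaResult]],
                               q_threshold: float = 0.05) -> pd.Series:
    """Per gene set, the number of diseases in which it is significant.

    Significance is BH-adjusted q < ``q_threshold`` (0.05 by default).
    """
    counts: dict[str, int] = {}
    for results in results_per_disease.values():
        for res in results:
            counts.setdefault(res.set_name, 0)
            if res.qvalue < q_threshold:
                counts[res.set_name] += 1
    return pd.Series(counts, name="n_significant_diseases").sort_index()
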