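"""Preranked gene-set enrichment with a gene-permutation null.

Genes are ranked by a signed per-gene statistic (moderated t or log2 fold
change). For a gene set the enrichment score (ES) is the signed extremum of a
weighted Kolmogorov–Smirnov running sum over the ranked list: walking down the
list, a hit increments the sum by |metric|^p normalised over the hits, a miss
decrements by 1/(N − n_hits). The null distribution is built by scoring random
gene sets of the same size (gene-label permutation — appropriate when the
sample size is far too small for sample permutation), with sign-stratified
p-values and normalisation: NES = ES / mean(|null ES| of the same sign), and an
add-one permutation p-value so p is never exactly zero. Benjamini–Hochberg
adjustment is applied across the sets of a collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from acnesig.diffexpr import ContrastResult, bh_adjust
from acnesig.io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes in descending metric order with their signed metric values."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.isnan(self.metric).any():
            raise ValueError("ranked list contains NaN metric values")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(result: ContrastResult, metric: str = "t_mod") -> RankedList:
    """Rank a contrast's genes by ``t_mod`` or ``log2fc``, descending.

    Ties are broken by gene ID ascending; NaN metric values are rejected.
    """
    column = {"t_mod": "t_mod", "log2fc": "delta_log2"}.get(metric)
    if column is None:
        raise ValueError(f"unknown metric {metric!r}; use 't_mod' or 'log2fc'")
    t = result.table
    values = t[column].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"metric {metric!r} contains NaN values")
    genes = t["gene"].to_numpy()
    # descending metric, ascending gene ID within ties
    order = np.lexsort((genes, -values))
    return RankedList([str(g) for g in genes[order]], values[order])


def enrichment_score(
    ranked: RankedList, gene_set, weight: int = 1
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score for one gene set.

    Set genes absent from the ranked list are dropped. Returns the signed ES
    (running-sum value of maximal absolute deviation; the first extremum on
    ties), the full running sum, and the leading-edge genes: the hits at or
    before the extremum for a positive ES, at or after it for a negative ES.
    """
    genes = getattr(gene_set, "genes", gene_set)
    members = set(genes)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool)
    n_hits = int(hits.sum())
    n = len(ranked)
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked list")

    weights = np.abs(ranked.metric) ** weight
    hit_weights = np.where(hits, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:
        # all hit metrics are exactly zero; fall back to unweighted steps
        hit_weights = hits.astype(float)
        total = hit_weights.sum()
    running = np.cumsum(hit_weights / total - (~hits) / (n - n_hits))
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        leading = [g for i, g in enumerate(ranked.genes) if hits[i] and i <= extremum]
    else:
        leading = [g for i, g in enumerate(ranked.genes) if hits[i] and i >= extremum]
    return es, running, leading


def _es_batch(weights: np.ndarray, hit_matrix: np.ndarray) -> np.ndarray:
    """ES for many same-size gene sets at once; rows of hit_matrix are sets."""
    n = weights.size
    n_hits = hit_matrix.sum(axis=1, keepdims=True)
    hit_w = hit_matrix * weights
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals == 0
    if zero.any():
        hit_w = np.where(zero, hit_matrix.astype(float), hit_w)
        totals = hit_w.sum(axis=1, keepdims=True)
    running = np.cumsum(hit_w / totals - (~hit_matrix) / (n - n_hits), axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: int = 1,
    seed: int | None = None,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over a collection with a random-gene-set null.

    For each set, ``n_perm`` random same-size gene sets are scored; the
    p-value compares |ES| with the null scores of the same sign (add-one
    rule), and NES divides ES by the mean |null ES| of that sign. Sets whose
    overlap with the ranked list falls outside [min_size, max_size] are
    skipped with a logged reason. Deterministic under a fixed seed.

    Returns a DataFrame indexed by set name with columns size_used, es, nes,
    p_perm, q_bh and leading_edge (comma-joined gene list).
    """
    if n_perm < 100:
        logger.warning("gsea_preranked: n_perm=%d < 100 gives unstable p-values", n_perm)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights = np.abs(ranked.metric) ** weight
    in_list = set(ranked.genes)

    rows = []
    for gene_set in collection:
        used = [g for g in gene_set.genes if g in in_list]
        k = len(used)
        if k == 0:
            logger.info("gsea_preranked: set %r skipped (no overlap)", gene_set.name)
            continue
        if not (min_size <= k <= max_size):
            logger.info(
                "gsea_preranked: set %r skipped (size_used %d outside [%d, %d])",
                gene_set.name,
                k,
                min_size,
                max_size,
            )
            continue
        es, _, leading = enrichment_score(ranked, used, weight)

        hit_matrix = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            hit_matrix[i, rng.choice(n, size=k, replace=False)] = True
        null_es = _es_batch(weights, hit_matrix)

        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        null_same = np.abs(null_es[same_sign])
        n_same = int(same_sign.sum())
        p_perm = (1 + int((null_same >= abs(es)).sum())) / (1 + n_same)
        denom = null_same.mean() if n_same > 0 else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        rows.append(
            {
                "set": gene_set.name,
                "size_used": k,
                "es": es,
                "nes": nes,
                "p_perm": p_perm,
                "leading_edge": ",".join(leading),
            }
        )

    result = pd.DataFrame(
        rows, columns=["set", "size_used", "es", "nes", "p_perm", "leading_edge"]
    )
    if len(result):
        result["q_bh"] = bh_adjust(result["p_perm"].to_numpy())
    else:
        result["q_bh"] = []
    return result.set_index("set", drop=False)[
        ["set", "size_used", "es", "nes", "p_perm", "q_bh", "leading_edge"]
    ]
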