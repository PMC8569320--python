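"""Low-expression filtering, normalisation utility, probe collapse, group means.

The filtering rule keeps a probe-set when at least ``min_samples`` samples of a
single condition group reach a log2 intensity of ``min_log2`` (default 6, i.e.
linear intensity 2^6) — the standard "expressed somewhere" screen for
RMA-normalised arrays. Group means are arithmetic means on log2 scale, which
equal the log2 of the geometric mean of the linear intensities; fold changes
are reported both as log2 differences and in the signed linear convention
(±2^|Δ|) used for readability in results tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from acnesig.io_formats import (
    CONDITIONS,
    ExpressionMatrix,
    ProbeGeneMap,
    SampleTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterRule:
    """Keep a feature if ≥ ``min_samples`` samples of one condition are ≥ ``min_log2``."""

    min_log2: float = 6.0
    min_samples: int = 5

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be a positive integer")


def filter_low_expression(
    m: ExpressionMatrix, samples: SampleTable, rule: FilterRule = FilterRule()
) -> ExpressionMatrix:
    """Apply the low-expression screen; feature order is preserved.

    The comparison is inclusive (``>=``) on both the intensity threshold and
    the sample count. Every sample of the matrix must be annotated in the
    sample table; an empty result is allowed (with a warning), not an error.
    """
    condition_of = samples.condition_of()
    missing = [s for s in m.sample_ids if s not in condition_of]
    if missing:
        raise ValueError(f"samples not annotated in sample table: {missing}")

    values = m.values.to_numpy()
    keep = np.zeros(m.shape[0], dtype=bool)
    for cond in CONDITIONS:
        cols = [j for j, s in enumerate(m.sample_ids) if condition_of[s] == cond]
        if not cols:
            continue
        counts = (values[:, cols] >= rule.min_log2).sum(axis=1)
        keep |= counts >= rule.min_samples
    if not keep.any():
        logger.warning("low-expression filter removed every feature")
    logger.info(
        "low-expression filter: kept %d of %d features", int(keep.sum()), m.shape[0]
    )
    return ExpressionMatrix(m.values.loc[keep])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-mean) reference distribution.

    Each column's sorted values are replaced by the across-column mean of the
    sorted input; tied values within a column receive the mean of the
    reference values their rank span covers. A single-column matrix is
    returned unchanged with a warning.
    """
    if m.shape[1] < 2:
        logger.warning("quantile_normalize: single-column input returned unchanged")
        return ExpressionMatrix(m.values.copy())
    values = m.values.to_numpy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        # average the reference over each tie group
        sorted_col = col[order]
        new_sorted = reference.copy()
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    new_sorted[start:end] = reference[start:end].mean()
                start = end
        out[:, j] = new_sorted[ranks]
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    )


def collapse_probes(
    m: ExpressionMatrix, probe_map: ProbeGeneMap, method: str = "max_mean_probe"
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene symbol.

    ``max_mean_probe`` keeps, per gene, the probe with the highest mean log2
    expression (ties broken by probe ID); ``gene_mean`` averages all probes of
    a gene. Probes absent from the map are dropped with a logged count.
    """
    if method not in ("max_mean_probe", "gene_mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    gene_of = probe_map.as_dict()
    mapped = [p for p in m.feature_ids if p in gene_of]
    n_dropped = m.shape[0] - len(mapped)
    if not mapped:
        raise ValueError("no overlap between matrix features and probe map")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)

    sub = m.values.loc[mapped]
    genes = pd.Series([gene_of[p] for p in mapped], index=sub.index, name="gene")
    if method == "gene_mean":
        collapsed = sub.groupby(genes, sort=True).mean()
    else:
        means = sub.mean(axis=1)
        # highest mean wins; ties resolved by probe ID
        best = (
            pd.DataFrame({"gene": genes, "mean": means, "probe": sub.index})
            .sort_values(["mean", "probe"], ascending=[False, True], kind="stable")
            .drop_duplicates("gene")
            .sort_values("gene")
        )
        collapsed = sub.loc[best["probe"]]
        collapsed.index = best["gene"].to_numpy()
    return ExpressionMatrix(collapsed)


def group_means(m: ExpressionMatrix, samples: SampleTable) -> pd.DataFrame:
    """Per-gene arithmetic mean of log2 values in each condition group.

    On log2 data this equals the log2 of the geometric mean of the linear
    intensities. Conditions with no samples are omitted; an empty group for a
    condition present in the table is impossible by construction.
    """
    condition_of = samples.condition_of()
    missing = [s for s in m.sample_ids if s not in condition_of]
    if missing:
        raise ValueError(f"samples not annotated in sample table: {missing}")
    out = {}
    for cond in CONDITIONS:
        cols = [s for s in m.sample_ids if condition_of[s] == cond]
        if cols:
            out[cond] = m.values[cols].mean(axis=1)
    if not out:
        raise ValueError("no condition group has any samples")
    return pd.DataFrame(out)


def signed_fold_change(delta_log2):
    """Signed linear fold change: 2^Δ for Δ ≥ 0, −2^(−Δ) for Δ < 0.

    This is the reporting convention in which a halving is −2 rather than 0.5;
    Δ = 0 maps to 1. Accepts scalars or arrays.
    """
    delta = np.asarray(delta_log2, dtype=float)
    out = np.where(delta >= 0, 2.0**delta, -(2.0 ** (-delta)))
    if np.isscalar(delta_log2) or np.ndim(delta_log2) == 0:
        return float(out)
    return out
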