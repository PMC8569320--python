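"""Contrast signatures, Venn partitioning, reversal patterns, gene clustering.

Three signatures describe the life cycle of an inflammatory papule: the papule
signature (baseline lesion vs non-involved skin, L1 vs L_NI), the vehicle
signature (spontaneously resolved lesion vs baseline lesion, L3 vs L1) and the
treatment signature (treated lesion vs baseline lesion, R3 vs L1). Their
candidate gene sets are partitioned into the 7 disjoint regions of a three-set
Venn diagram; genes specific to the treatment signature are classified by
whether their lesion induction is reversed by treatment. For heatmap display,
gene profiles restricted to selected conditions are z-scored and ordered by
average-linkage (UPGMA) hierarchical clustering under correlation distance;
samples are never clustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from acnesig.diffexpr import (
    STUDY_CONTRASTS,
    ContrastResult,
    run_contrast,
    select_candidates,
)
from acnesig.io_formats import ExpressionMatrix, SampleTable
from acnesig.synthetic import REGIONS

logger = logging.getLogger(__name__)


@dataclass
class SignaturePartition:
    """The 7 disjoint regions of the three-signature Venn diagram.

    ``regions`` maps each region name to its gene set; regions are pairwise
    disjoint and their union equals the union of the three input sets.
    ``provenance`` records the input contrast names and thresholds.
    """

    regions: dict[str, set[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.regions) != set(REGIONS):
            raise ValueError(f"partition must define exactly the regions {REGIONS}")

    @property
    def sizes(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return out


def derive_signatures(
    m: ExpressionMatrix,
    samples: SampleTable,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    d0: float | None = None,
) -> dict[str, tuple[ContrastResult, dict[str, int]]]:
    """Run the three study contrasts and select candidates with shared thresholds.

    Returns contrast name → (ContrastResult, candidate gene → direction).
    """
    out: dict[str, tuple[ContrastResult, dict[str, int]]] = {}
    for contrast in STUDY_CONTRASTS:
        result = run_contrast(m, samples, contrast, d0=d0)
        out[contrast.name] = (
            result,
            select_candidates(result, fc_threshold, q_threshold),
        )
    return out


def venn_partition(
    papule: set[str] | dict,
    vehicle: set[str] | dict,
    trifarotene: set[str] | dict,
    provenance: dict | None = None,
) -> SignaturePartition:
    """Exact three-set Venn partition of the candidate gene sets."""
    a, b, c = set(papule), set(vehicle), set(trifarotene)
    regions = {
        "papule_only": a - b - c,
        "vehicle_only": b - a - c,
        "trifarotene_only": c - a - b,
        "papule_vehicle": (a & b) - c,
        "papule_trifarotene": (a & c) - b,
        "vehicle_trifarotene": (b & c) - a,
        "all_three": a & b & c,
    }
    return SignaturePartition(regions, provenance or {})


def classify_reversal(
    partition: SignaturePartition,
    papule_result: ContrastResult,
    trifarotene_result: ContrastResult,
) -> dict[str, str]:
    """Reversal pattern of each treatment-specific gene.

    ``up_in_papule_down_after_treatment`` when the papule log2FC is positive
    and the treatment log2FC negative; the mirror pattern symmetrically;
    everything else (including a zero papule effect) is ``other``.
    """
    out: dict[str, str] = {}
    for gene in sorted(partition.regions["trifarotene_only"]):
        for result in (papule_result, trifarotene_result):
            if gene not in result.table.index:
                raise KeyError(
                    f"gene {gene!r} missing from contrast result {result.name!r}"
                )
        d_pap = papule_result.table.loc[gene, "delta_log2"]
        d_tri = trifarotene_result.table.loc[gene, "delta_log2"]
        if d_pap > 0 and d_tri < 0:
            out[gene] = "up_in_papule_down_after_treatment"
        elif d_pap < 0 and d_tri > 0:
            out[gene] = "down_in_papule_up_after_treatment"
        else:
            out[gene] = "other"
    return out


def _correlation_distance(z: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Pearson distance; zero-variance rows get correlation 0."""
    sd = z.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "cluster_genes: %d zero-variance gene rows; their correlation is "
            "treated as 0 (distance 1)",
            int(degenerate.sum()),
        )
    centered = z - z.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def cluster_genes(
    m: ExpressionMatrix,
    samples: SampleTable,
    genes: list[str],
    conditions: tuple[str, ...] = ("L_NI", "L1", "R3"),
) -> tuple[list[str], np.ndarray]:
    """Order genes for heatmap display by UPGMA under correlation distance.

    Each gene's profile over the samples of the chosen conditions is z-scored
    (mean 0, sd 1); the pairwise distance is 1 − Pearson correlation of the
    scaled rows; merging uses average linkage. Samples are not clustered.
    Genes are processed in lexicographic order so the result is invariant to
    the input order (up to exact distance ties). Returns (leaf order, linkage
    matrix in scipy format).
    """
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("cluster_genes needs at least 2 genes")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    condition_of = samples.condition_of()
    cols = [s for s in m.sample_ids if condition_of.get(s) in conditions]
    if not cols:
        raise ValueError(f"no samples found for conditions {conditions}")

    sub = m.values.loc[genes, cols].to_numpy()
    sd = sub.std(axis=1, ddof=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (sub - sub.mean(axis=1, keepdims=True)) / safe_sd[:, None]
    dist = _correlation_distance(z)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(linkage)
    return [genes[i] for i in order], linkage
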