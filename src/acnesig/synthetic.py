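"""Synthetic paired multi-condition expression studies with planted ground truth.

The generator emulates a paired clinical design: each of ``n_subjects`` subjects
contributes one biopsy per condition — non-involved skin (L_NI), baseline lesion
(L1), vehicle-resolved lesion (L3) and treated lesion (R3). Per gene *g*,
subject *s* and condition *c* the log2 expression is

    y[g, s, c] = mu_g + b[g, s] + delta[g, c] + m[g, c] + eps

with ``b[g, s] ~ N(0, subject_sd^2)`` a gene-level subject random effect,
``eps ~ N(0, sigma_g^2)`` measurement noise whose per-gene variance is drawn
from a scaled-inverse-chi-square prior (so the empirical-Bayes variance
estimator downstream has a recoverable target), ``delta`` the planted
differential-expression effects and ``m`` additive cell-type panel shifts.

Differential expression is planted per Venn region over the three contrasts of
interest (papule: L1 vs L_NI; vehicle: L3 vs L1; treatment: R3 vs L1). A gene
assigned to a region carries an effect of magnitude ``effect_log2fc`` in
exactly the contrasts of that region. Each planted gene draws a lesion
direction (up with probability ``direction_up_fraction``); its papule effect
follows that direction while resolution-contrast effects are mirrored,
emulating lesion genes whose induction is reversed by resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from acnesig.io_formats import (
    CONDITIONS,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
)

#: The 7 disjoint regions of the three-signature Venn diagram, keyed by which
#: contrasts a member gene is differentially expressed in.
REGIONS: tuple[str, ...] = (
    "papule_only",
    "vehicle_only",
    "trifarotene_only",
    "papule_vehicle",
    "papule_trifarotene",
    "vehicle_trifarotene",
    "all_three",
)

#: Contrast membership of each region: (papule, vehicle, trifarotene).
REGION_CONTRASTS: dict[str, tuple[bool, bool, bool]] = {
    "papule_only": (True, False, False),
    "vehicle_only": (False, True, False),
    "trifarotene_only": (False, False, True),
    "papule_vehicle": (True, True, False),
    "papule_trifarotene": (True, False, True),
    "vehicle_trifarotene": (False, True, True),
    "all_three": (True, True, True),
}

CONTRAST_NAMES: tuple[str, str, str] = ("papule", "vehicle", "trifarotene")


@dataclass
class StudyDesignConfig:
    """Parameters of one simulated paired study.

    Defaults mirror the clinical design being emulated: 9 subjects × 4 biopsy
    conditions, log2 baselines uniform in [4, 12], subject standard deviation
    0.3 and residual noise 0.4 on log2 scale — variability typical of
    RMA-normalised arrays. ``var_prior_df`` is the degrees of freedom of the
    scaled-inverse-chi-square prior from which per-gene noise variances are
    drawn (scale = ``noise_sd**2``); set it to ``inf`` for homoscedastic noise.
    """

    n_subjects: int = 9
    n_genes: int = 2000
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    subject_sd: float = 0.3
    noise_sd: float = 0.4
    venn_region_sizes: Mapping[str, int] = field(default_factory=dict)
    effect_log2fc: float = 2.0
    direction_up_fraction: float = 0.8
    var_prior_df: float = 4.0
    celltype_panels: GeneSetCollection | None = None
    celltype_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_genes < 1:
            raise ValueError("n_subjects and n_genes must be positive")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        unknown = set(self.venn_region_sizes) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown Venn region name(s): {sorted(unknown)}")
        if any(v < 0 for v in self.venn_region_sizes.values()):
            raise ValueError("venn_region_sizes must be non-negative")
        if sum(self.venn_region_sizes.values()) > self.n_genes:
            raise ValueError(
                f"sum of venn_region_sizes "
                f"({sum(self.venn_region_sizes.values())}) exceeds n_genes "
                f"({self.n_genes})"
            )
        if not 0.0 <= self.direction_up_fraction <= 1.0:
            raise ValueError("direction_up_fraction must be in [0, 1]")
        for (cell, cond) in self.celltype_shift:
            if self.celltype_panels is None or cell not in self.celltype_panels.names:
                raise ValueError(f"celltype_shift names unknown panel {cell!r}")
            if cond not in CONDITIONS:
                raise ValueError(f"celltype_shift names unknown condition {cond!r}")


@dataclass
class GroundTruth:
    """Planted truth for one simulated study.

    ``genes`` has one row per gene: its Venn region (``none`` for nulls) and
    the planted direction (+1/−1/0) in each of the three contrasts.
    ``reversal`` gives, for every planted gene, the expected pattern under the
    sign-based reversal classification (papule effect up and treatment effect
    down, the mirror, or ``other``). ``celltype_shift`` echoes the planted
    panel shifts.
    """

    genes: pd.DataFrame  # columns: gene, region, dir_papule, dir_vehicle, dir_trifarotene
    celltype_shift: dict[tuple[str, str], float]

    def region_genes(self, region: str) -> set[str]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        mask = self.genes["region"] == region
        return set(self.genes.loc[mask, "gene"])

    def contrast_genes(self, contrast: str) -> set[str]:
        """All genes planted as DE in one contrast (any region containing it)."""
        idx = CONTRAST_NAMES.index(contrast)
        keep = [r for r, flags in REGION_CONTRASTS.items() if flags[idx]]
        mask = self.genes["region"].isin(keep)
        return set(self.genes.loc[mask, "gene"])

    @property
    def reversal(self) -> pd.Series:
        """Expected reversal pattern per planted gene, from planted signs."""
        planted = self.genes[self.genes["region"] != "none"]
        out = {}
        for _, row in planted.iterrows():
            if row["dir_papule"] > 0 and row["dir_trifarotene"] < 0:
                out[row["gene"]] = "up_in_papule_down_after_treatment"
            elif row["dir_papule"] < 0 and row["dir_trifarotene"] > 0:
                out[row["gene"]] = "down_in_papule_up_after_treatment"
            else:
                out[row["gene"]] = "other"
        return pd.Series(out, dtype=object)

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def _gene_ids(config: StudyDesignConfig) -> list[str]:
    """Feature IDs: marker-panel genes first (if any), then synthetic IDs."""
    ids: list[str] = []
    if config.celltype_panels is not None:
        seen: set[str] = set()
        for panel in config.celltype_panels:
            for g in panel.genes:
                if g not in seen:
                    ids.append(g)
                    seen.add(g)
    if len(ids) > config.n_genes:
        raise ValueError(
            f"celltype panels contain {len(ids)} distinct genes but n_genes is "
            f"{config.n_genes}"
        )
    width = max(4, len(str(config.n_genes)))
    i = 0
    while len(ids) < config.n_genes:
        gid = f"G{i:0{width}d}"
        if config.celltype_panels is None or gid not in ids:
            ids.append(gid)
        i += 1
    return ids


def simulate_study(
    config: StudyDesignConfig,
) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Simulate one paired study; a fixed seed gives bit-identical output.

    Planted DE genes are drawn from the non-marker features so that cell-type
    panel shifts and contrast effects never overlap. Returns the log2
    expression matrix (genes × subjects·conditions), the sample annotation and
    the planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = _gene_ids(config)
    n_genes = config.n_genes
    n_sub = config.n_subjects

    subjects = [f"S{j + 1:02d}" for j in range(n_sub)]
    sample_rows = [
        (f"{s}_{c}", s, c) for s in subjects for c in CONDITIONS
    ]
    samples = SampleTable(
        pd.DataFrame(sample_rows, columns=["sample_id", "subject_id", "condition"])
    )

    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=n_genes)
    b = (
        rng.normal(0.0, config.subject_sd, size=(n_genes, n_sub))
        if config.subject_sd > 0
        else np.zeros((n_genes, n_sub))
    )

    # Per-gene noise variance ~ scaled-inverse-chi-square(var_prior_df, noise_sd^2).
    if config.noise_sd == 0:
        sigma = np.zeros(n_genes)
    elif math.isinf(config.var_prior_df):
        sigma = np.full(n_genes, config.noise_sd)
    else:
        d0 = config.var_prior_df
        s2 = d0 * config.noise_sd**2 / rng.chisquare(d0, size=n_genes)
        sigma = np.sqrt(s2)

    # Assign Venn regions to genes drawn from the non-marker features.
    marker_count = 0
    if config.celltype_panels is not None:
        marker_count = len(
            {g for panel in config.celltype_panels for g in panel.genes}
        )
    eligible = np.arange(marker_count, n_genes)
    total_planted = sum(config.venn_region_sizes.get(r, 0) for r in REGIONS)
    if total_planted > len(eligible):
        raise ValueError(
            "not enough non-marker genes to plant all Venn regions: "
            f"{total_planted} planted vs {len(eligible)} eligible"
        )
    chosen = rng.choice(eligible, size=total_planted, replace=False)
    region_of = np.full(n_genes, "none", dtype=object)
    pos = 0
    for region in REGIONS:
        k = config.venn_region_sizes.get(region, 0)
        region_of[chosen[pos : pos + k]] = region
        pos += k

    # Planted directions: lesion direction d (up w.p. direction_up_fraction);
    # papule effect follows d, resolution-contrast effects are mirrored (−d).
    lesion_dir = np.where(
        rng.random(n_genes) < config.direction_up_fraction, 1, -1
    )
    dirs = np.zeros((n_genes, 3), dtype=int)
    for idx, contrast in enumerate(CONTRAST_NAMES):
        member = np.array(
            [r != "none" and REGION_CONTRASTS[r][idx] for r in region_of]
        )
        sign = lesion_dir if contrast == "papule" else -lesion_dir
        dirs[member, idx] = sign[member]

    # Condition offsets reproducing each planted contrast effect exactly:
    # delta(L_NI)=0, delta(L1)=e_pap, delta(L3)=e_pap+e_veh, delta(R3)=e_pap+e_tri.
    eff = config.effect_log2fc
    e_pap = dirs[:, 0] * eff
    e_veh = dirs[:, 1] * eff
    e_tri = dirs[:, 2] * eff
    delta = {
        "L_NI": np.zeros(n_genes),
        "L1": e_pap,
        "L3": e_pap + e_veh,
        "R3": e_pap + e_tri,
    }

    # Cell-type panel shifts: additive on every marker gene of the panel.
    shift = {c: np.zeros(n_genes) for c in CONDITIONS}
    if config.celltype_panels is not None:
        index_of = {g: i for i, g in enumerate(gene_ids)}
        for (cell, cond), amount in config.celltype_shift.items():
            for g in config.celltype_panels[cell].genes:
                shift[cond][index_of[g]] += amount

    data = np.empty((n_genes, len(sample_rows)))
    for col, (_, subject, cond) in enumerate(sample_rows):
        s_idx = subjects.index(subject)
        noise = (
            rng.normal(0.0, 1.0, size=n_genes) * sigma
            if config.noise_sd > 0
            else 0.0
        )
        data[:, col] = mu + b[:, s_idx] + delta[cond] + shift[cond] + noise

    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=gene_ids, columns=[r[0] for r in sample_rows])
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene": gene_ids,
                "region": region_of,
                "dir_papule": dirs[:, 0],
                "dir_vehicle": dirs[:, 1],
                "dir_trifarotene": dirs[:, 2],
            }
        ),
        celltype_shift=dict(config.celltype_shift),
    )
    return matrix, samples, truth


def simulate_null_study(
    n_subjects: int = 9, n_genes: int = 2000, seed: int = 0
) -> tuple[ExpressionMatrix, SampleTable]:
    """A study with no planted effects at all — the type-I-error harness."""
    config = StudyDesignConfig(
        n_subjects=n_subjects, n_genes=n_genes, seed=seed
    )
    matrix, samples, _ = simulate_study(config)
    return matrix, samples
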