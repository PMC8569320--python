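"""End-to-end orchestration: study in → signatures, enrichment and cell scores out.

A run is driven by one YAML config (validated up front, unknown keys rejected)
and one seed. Per-stage random streams are derived from that seed, so e.g.
changing the number of GSEA permutations never perturbs the simulated study.
Every stage writes plain-text artifacts into the output directory and a
machine-readable JSON run report records versions, the echoed config,
per-stage summaries and timings. Conservation checks (filter in/out counts,
Venn region sizes summing to the union) are asserted at run time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import acnesig
from acnesig.celltype import builtin_marker_panels, compare_groups, score_samples
from acnesig.enrichment import gsea_preranked, rank_genes
from acnesig.io_formats import (
    GeneSet,
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
    read_sample_table,
    write_expression_matrix,
    write_sample_table,
)
from acnesig.preprocess import FilterRule, filter_low_expression
from acnesig.signatures import (
    classify_reversal,
    cluster_genes,
    derive_signatures,
    venn_partition,
)
from acnesig.synthetic import REGIONS, StudyDesignConfig, simulate_study

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run config is structurally invalid."""


_THRESHOLD_DEFAULTS = {"min_log2": 6.0, "min_samples": 5, "fc": 2.0, "fdr": 0.05}
_GSEA_DEFAULTS = {"gmt": None, "n_perm": 1000, "weight": 1, "min_size": 5, "max_size": 500}
_SIM_KEYS = {
    "n_subjects",
    "n_genes",
    "baseline_mean_range",
    "subject_sd",
    "noise_sd",
    "venn_region_sizes",
    "effect_log2fc",
    "direction_up_fraction",
    "var_prior_df",
    "celltype_shift",
    "use_builtin_panels",
}
_TOP_KEYS = {"seed", "out_dir", "input", "simulate", "thresholds", "gsea", "panels"}


@dataclass
class RunConfig:
    """Fully validated pipeline configuration with defaults applied."""

    seed: int = 0
    out_dir: str = "acnesig_out"
    input: dict[str, str] | None = None  # {"matrix": path, "samples": path}
    simulate: dict[str, Any] | None = None
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_THRESHOLD_DEFAULTS)
    )
    gsea: dict[str, Any] = field(default_factory=lambda: dict(_GSEA_DEFAULTS))
    panels: str = "builtin"


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run config before any compute.

    Unknown keys anywhere are errors (typo protection); required keys are
    reported by name; defaults are filled in and echoed in the run report.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    has_input = raw.get("input") is not None
    has_sim = raw.get("simulate") is not None
    if has_input == has_sim:
        raise ConfigError("config must provide exactly one of 'input' or 'simulate'")

    cfg = RunConfig(
        seed=int(raw.get("seed", 0)), out_dir=str(raw.get("out_dir", "acnesig_out"))
    )

    if has_input:
        _check_keys(raw["input"], {"matrix", "samples"}, "input")
        for key in ("matrix", "samples"):
            if key not in raw["input"]:
                raise ConfigError(f"input section missing required key {key!r}")
            if not Path(raw["input"][key]).exists():
                raise ConfigError(f"input file does not exist: {raw['input'][key]}")
        cfg.input = dict(raw["input"])
    else:
        _check_keys(raw["simulate"], _SIM_KEYS, "simulate")
        cfg.simulate = dict(raw["simulate"])

    thresholds = dict(_THRESHOLD_DEFAULTS)
    if raw.get("thresholds"):
        _check_keys(raw["thresholds"], set(_THRESHOLD_DEFAULTS), "thresholds")
        thresholds.update(raw["thresholds"])
    if not 0 < thresholds["fdr"] <= 1:
        raise ConfigError("fdr threshold must be in (0, 1]")
    if thresholds["fc"] < 1:
        raise ConfigError("fc threshold must be >= 1")
    cfg.thresholds = thresholds

    gsea = dict(_GSEA_DEFAULTS)
    if raw.get("gsea"):
        _check_keys(raw["gsea"], set(_GSEA_DEFAULTS), "gsea")
        gsea.update(raw["gsea"])
        if gsea["gmt"] is not None and not Path(gsea["gmt"]).exists():
            raise ConfigError(f"GMT file does not exist: {gsea['gmt']}")
    cfg.gsea = gsea

    panels = raw.get("panels", "builtin")
    if panels != "builtin" and not Path(panels).exists():
        raise ConfigError(f"panels must be 'builtin' or an existing GMT path: {panels}")
    cfg.panels = panels
    return cfg


def _shift_key(key) -> tuple[str, str]:
    """Normalise a celltype_shift key: (panel, condition) tuple/list, or the
    YAML-friendly string form ``"panel|condition"``."""
    if isinstance(key, tuple) and len(key) == 2:
        return key
    if isinstance(key, list) and len(key) == 2:
        return (key[0], key[1])
    if isinstance(key, str) and "|" in key:
        cell, cond = key.rsplit("|", 1)
        return (cell, cond)
    raise ConfigError(
        f"celltype_shift key {key!r} must be (panel, condition) or 'panel|condition'"
    )


def _stage_seeds(seed: int, n: int = 2) -> list[int]:
    """Independent per-stage substream seeds derived from the config seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def demo_config(out_dir: str | Path = "acnesig_demo", seed: int = 7) -> RunConfig:
    """The bundled synthetic study.

    9 subjects, planted Venn regions, and cell-type shifts emulating lesion
    immune infiltration, spontaneous partial resolution, and
    treatment-specific restoration of the SPP1+ macrophage score.
    """
    immune_up = {
        ("B cells", "L1"): 1.5,
        ("T cells", "L1"): 1.5,
        ("Myeloid cells", "L1"): 1.5,
        ("M0 macrophage", "L1"): 1.5,
        ("M1 macrophage", "L1"): 1.5,
        ("M2 macrophage", "L1"): 1.5,
        ("SPP1 macrophage", "L1"): 1.5,
        # spontaneous resolution clears most infiltrate but not SPP1+ macrophages
        ("M0 macrophage", "L3"): 0.3,
        ("M1 macrophage", "L3"): 0.3,
        ("M2 macrophage", "L3"): 0.3,
        ("SPP1 macrophage", "L3"): 1.5,
    }
    cfg = RunConfig(seed=seed, out_dir=str(out_dir))
    cfg.simulate = {
        "n_subjects": 9,
        "n_genes": 1200,
        "venn_region_sizes": {
            "papule_only": 10,
            "vehicle_only": 10,
            "trifarotene_only": 10,
            "papule_vehicle": 5,
            "papule_trifarotene": 5,
            "vehicle_trifarotene": 5,
            "all_three": 5,
        },
        "effect_log2fc": 3.0,
        "noise_sd": 0.3,
        "use_builtin_panels": True,
        "celltype_shift": immune_up,
    }
    return cfg


def _demo_gene_sets(truth, rng: np.random.Generator, n_random: int = 10) -> GeneSetCollection:
    """Gene sets for the GSEA stage of a simulated run.

    Each planted contrast's gene set plus random decoy sets drawn from the
    simulated gene universe.
    """
    all_genes = list(truth.genes["gene"])
    sets = []
    for contrast in ("papule", "vehicle", "trifarotene"):
        genes = tuple(sorted(truth.contrast_genes(contrast)))
        if genes:
            sets.append(GeneSet(f"planted_{contrast}", "planted DE genes", genes))
    for i in range(n_random):
        genes = tuple(sorted(rng.choice(all_genes, size=20, replace=False)))
        sets.append(GeneSet(f"random_{i:02d}", "random decoy set", genes))
    return GeneSetCollection(sets)


def _jsonable_sim(sim: dict | None) -> dict | None:
    """Echo the simulate section with JSON-safe celltype_shift keys."""
    if sim is None:
        return None
    out = dict(sim)
    if "celltype_shift" in out:
        out["celltype_shift"] = {
            "|".join(_shift_key(k)): v for k, v in out["celltype_shift"].items()
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written to disk).

    Stages: load-or-simulate → low-expression filter → three paired contrasts
    → candidate selection → Venn partition → reversal classification → gene
    clustering of the treatment-specific set → preranked GSEA → cell-type
    scoring and group comparisons.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_seed, gsea_seed = _stage_seeds(config.seed, 2)
    report: dict[str, Any] = {
        "versions": {
            "acnesig": acnesig.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            "seed": config.seed,
            "out_dir": str(config.out_dir),
            "input": config.input,
            "simulate": _jsonable_sim(config.simulate),
            "thresholds": config.thresholds,
            "gsea": dict(config.gsea),
            "panels": config.panels,
        },
        "stages": {},
        "warnings": [],
    }
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- load or simulate -------------------------------------------------
    truth = None
    demo_sets: GeneSetCollection | None = None
    if config.input is not None:
        matrix = read_expression_matrix(config.input["matrix"])
        samples = read_sample_table(config.input["samples"])
    else:
        sim = dict(config.simulate or {})
        use_builtin = sim.pop("use_builtin_panels", False)
        shift = {
            _shift_key(k): float(v) for k, v in sim.pop("celltype_shift", {}).items()
        }
        sim_cfg = StudyDesignConfig(
            **sim,
            celltype_panels=builtin_marker_panels() if use_builtin else None,
            celltype_shift=shift,
            seed=sim_seed,
        )
        matrix, samples, truth = simulate_study(sim_cfg)
        write_expression_matrix(matrix, out_dir / "simulated_matrix.tsv")
        write_sample_table(samples, out_dir / "simulated_samples.tsv")
        truth.to_tsv(out_dir / "ground_truth.tsv")
        demo_sets = _demo_gene_sets(truth, np.random.default_rng(gsea_seed))
    report["stages"]["data"] = {
        "n_features": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "simulated": config.input is None,
    }
    timings["data"] = time.perf_counter() - t0

    # --- low-expression filter -------------------------------------------
    t0 = time.perf_counter()
    rule = FilterRule(
        min_log2=float(config.thresholds["min_log2"]),
        min_samples=int(config.thresholds["min_samples"]),
    )
    filtered = filter_low_expression(matrix, samples, rule)
    assert filtered.shape[0] <= matrix.shape[0]
    report["stages"]["filter"] = {
        "n_in": matrix.shape[0],
        "n_out": filtered.shape[0],
        "min_log2": rule.min_log2,
        "min_samples": rule.min_samples,
    }
    timings["filter"] = time.perf_counter() - t0

    # --- three contrasts and candidate sets -------------------------------
    t0 = time.perf_counter()
    fc = float(config.thresholds["fc"])
    fdr = float(config.thresholds["fdr"])
    sig = derive_signatures(filtered, samples, fc_threshold=fc, q_threshold=fdr)
    de_summary = {}
    for name, (result, candidates) in sig.items():
        result.table.to_csv(out_dir / f"de_{name}.tsv", sep="\t", index=False)
        de_summary[name] = {
            "n_candidates": len(candidates),
            "d0": result.d0,
            "s0_sq": result.s0_sq,
            "n_pairs": result.n_pairs,
        }
    report["stages"]["diffexpr"] = de_summary
    timings["diffexpr"] = time.perf_counter() - t0

    # --- Venn partition, reversal, clustering ------------------------------
    t0 = time.perf_counter()
    partition = venn_partition(
        sig["papule"][1],
        sig["vehicle"][1],
        sig["trifarotene"][1],
        provenance={"fc": fc, "fdr": fdr},
    )
    sizes = partition.sizes
    assert sum(sizes.values()) == len(
        partition.union
    ), "Venn partition must conserve the union"
    with open(out_dir / "venn_partition.json", "w", encoding="utf-8") as fh:
        json.dump({r: sorted(partition.regions[r]) for r in REGIONS}, fh, indent=2)
        fh.write("\n")
    pd.DataFrame(
        [(r, g) for r in REGIONS for g in sorted(partition.regions[r])],
        columns=["region", "gene"],
    ).to_csv(out_dir / "venn_regions.tsv", sep="\t", index=False)

    reversal = classify_reversal(partition, sig["papule"][0], sig["trifarotene"][0])
    pd.Series(reversal, name="pattern", dtype=object).rename_axis("gene").to_csv(
        out_dir / "reversal.tsv", sep="\t"
    )
    reversal_counts = pd.Series(reversal, dtype=object).value_counts().to_dict()

    leaf_order: list[str] = []
    tri_genes = sorted(partition.regions["trifarotene_only"])
    if len(tri_genes) >= 2:
        leaf_order, _ = cluster_genes(filtered, samples, tri_genes)
        pd.Series(leaf_order, name="gene").to_csv(
            out_dir / "cluster_leaf_order.tsv", sep="\t", index=False
        )
    report["stages"]["signatures"] = {
        "region_sizes": sizes,
        "union_size": len(partition.union),
        "reversal_counts": reversal_counts,
        "n_clustered": len(leaf_order),
    }
    timings["signatures"] = time.perf_counter() - t0

    # --- preranked GSEA ----------------------------------------------------
    t0 = time.perf_counter()
    if config.gsea["gmt"] is not None:
        collection = read_gmt(config.gsea["gmt"])
    else:
        collection = demo_sets  # planted + decoy sets for simulated runs
    gsea_summary: dict[str, Any] = {"n_sets": 0}
    if collection is not None and len(collection):
        tested = {}
        for name, (result, _) in sig.items():
            ranked = rank_genes(result, metric="t_mod")
            gres = gsea_preranked(
                ranked,
                collection,
                n_perm=int(config.gsea["n_perm"]),
                weight=int(config.gsea["weight"]),
                seed=gsea_seed,
                min_size=int(config.gsea["min_size"]),
                max_size=int(config.gsea["max_size"]),
            )
            gres.to_csv(out_dir / f"gsea_{name}.tsv", sep="\t", index=False)
            tested[name] = int(len(gres))
        gsea_summary = {"n_sets": len(collection), "tested_per_contrast": tested}
    report["stages"]["gsea"] = gsea_summary
    timings["gsea"] = time.perf_counter() - t0

    # --- cell-type scoring --------------------------------------------------
    t0 = time.perf_counter()
    panels = (
        builtin_marker_panels() if config.panels == "builtin" else read_gmt(config.panels)
    )
    celltype_summary: dict[str, Any] = {"n_panels_scored": 0}
    try:
        scores = score_samples(filtered, panels)
    except ValueError as err:
        logger.warning("cell-type scoring skipped: %s", err)
        report["warnings"].append(f"celltype: {err}")
        scores = None
    if scores is not None:
        scores.scores.rename_axis("panel").to_csv(
            out_dir / "celltype_scores.tsv", sep="\t"
        )
        comparisons = compare_groups(scores, samples)
        comparisons.to_csv(out_dir / "celltype_comparisons.tsv", sep="\t", index=False)
        celltype_summary = {
            "n_panels_scored": int(scores.scores.shape[0]),
            "n_comparisons": int(len(comparisons)),
            "significant": int((comparisons["p"] < 0.05).sum()),
        }
    report["stages"]["celltype"] = celltype_summary
    timings["celltype"] = time.perf_counter() - t0

    report["timings_sec"] = {k: round(v, 4) for k, v in timings.items()}
    with open(out_dir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
        fh.write("\n")
    return report
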