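# acnesig

Differential-expression signatures of inflammatory acne lesions and their
reversal under topical retinoid treatment, on paired microarray-style data.

## The scientific problem

In a paired within-subject design, each subject contributes four skin
biopsies: non-involved skin (`L_NI`), a baseline acne papule (`L1`), a
vehicle-treated papule that resolved spontaneously (`L3`), and a
retinoid-treated papule (`R3`). Three paired contrasts describe the lesion
life cycle:

| contrast      | comparison    | question                                   |
|---------------|---------------|--------------------------------------------|
| `papule`      | `L1` vs `L_NI`| what does the lesion induce?               |
| `vehicle`     | `L3` vs `L1`  | what resolves spontaneously?               |
| `trifarotene` | `R3` vs `L1`  | what does treatment change?                |

The analysis asks which genes are changed by treatment **only** (the
treatment-specific signature), whether those genes show a *reversal* pattern
(up in the lesion, down after treatment, or the mirror), which gene sets are
enriched along each contrast, and how marker-panel scores for immune cell
types (including SPP1⁺ macrophages) move across the four conditions.

With only 9 subjects, per-gene variance estimates are unstable; the package
uses empirical-Bayes moderated t-statistics: per gene,

```
s²_post = (d0·s0² + df·s²) / (d0 + df),    t = mean(diff) / sqrt(s²_post / n)
```

with the prior `(d0, s0²)` estimated by matching the moments of `log s²`, and
p-values from a t distribution on `d0 + df` degrees of freedom. Candidate
genes satisfy |fold change| > 2 and Benjamini–Hochberg FDR < 0.05; the three
candidate sets are partitioned into the 7 disjoint regions of a three-set
Venn diagram.

Because real microarray data are large and noisy, the package ships a
synthetic study generator with planted ground truth (per-region effects,
variance prior, cell-type panel shifts), which makes every statistical claim
checkable: recovery, calibration and power are measured against known truth.

## Worked example

```python
from acnesig.synthetic import StudyDesignConfig, simulate_study
from acnesig.signatures import derive_signatures, venn_partition

cfg = StudyDesignConfig(
    n_subjects=9, n_genes=600,
    venn_region_sizes={"papule_only": 10, "trifarotene_only": 10, "all_three": 5},
    effect_log2fc=3.0, noise_sd=0.3, seed=42,
)
matrix, samples, truth = simulate_study(cfg)
sig = derive_signatures(matrix, samples)
for name, (result, candidates) in sig.items():
    print(f"{name}: {len(candidates)} candidates  "
          f"(d0={result.d0:.2f}, s0^2={result.s0_sq:.4f}, n_pairs={result.n_pairs})")
part = venn_partition(sig["papule"][1], sig["vehicle"][1], sig["trifarotene"][1])
print({r: len(g) for r, g in part.regions.items()})
```

prints

```
papule: 15 candidates  (d0=4.49, s0^2=0.1713, n_pairs=9)
vehicle: 5 candidates  (d0=4.31, s0^2=0.1734, n_pairs=9)
trifarotene: 15 candidates  (d0=4.38, s0^2=0.1686, n_pairs=9)
{'papule_only': 10, 'vehicle_only': 0, 'trifarotene_only': 10, 'papule_vehicle': 0,
 'papule_trifarotene': 0, 'vehicle_trifarotene': 0, 'all_three': 5}
```

All 25 planted genes are recovered exactly (the simulation planted 10
papule-only, 10 trifarotene-only, and 5 shared genes; the variance prior
`d0 = 4` and paired-difference scale `2 · 0.3² ≈ 0.18` are also recovered).

### The demo pipeline

```bash
acnesig demo --out-dir demo_out --seed 7
```

runs the complete pipeline on a bundled synthetic study (9 subjects, 1200
genes, planted Venn regions plus immune-infiltration marker shifts) in a few
seconds, writing DE tables, the Venn partition, reversal classifications, GSEA
results, cell-type scores and a `run_report.json`. With seed 7 the report
shows 945/1200 features passing the low-expression filter and the region
sizes

```
{'papule_only': 11, 'vehicle_only': 8, 'trifarotene_only': 9, 'papule_vehicle': 5,
 'papule_trifarotene': 15, 'vehicle_trifarotene': 5, 'all_three': 88}
```

— the large `all_three` region is the planted immune-marker infiltration that
resolves both spontaneously and under treatment, and 5 of the 9 recovered
treatment-specific genes classify as up-in-papule/down-after-treatment
reversals. Outputs are bit-identical across runs with the same seed.

`acnesig run --config run.yaml` drives the same pipeline from a YAML config
(simulated or loaded input); `acnesig simulate / preprocess / de / signatures
/ gsea / celltype` expose the individual stages.

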