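# Methods

## Data model and conventions

All expression values are on log2 scale (RMA-style normalized intensities);
thresholds such as the low-expression cutoff 2^6 are interpreted on that
convention. The design is paired: every subject contributes one sample per
condition (`L_NI`, `L1`, `L3`, `R3`), and each two-condition contrast is
analysed on within-subject differences, which is exactly the subject-blocked
linear model for that contrast. Missing values are hard errors, never
imputed; subjects missing a condition are dropped from that contrast with a
logged list.

## Preprocessing

- **Low-expression filter**: keep a feature if its log2 value is ≥ `min_log2`
  (default 6.0) in at least `min_samples` (default 5) samples of at least one
  condition. Both comparisons are inclusive. Defaults reflect a conventional
  "expressed above background in most of one group" rule for 9-subject
  groups.
- **Quantile normalization**: reference distribution is the row-sorted
  per-rank mean; ties receive the mean of the reference values their rank
  range spans, making the transform idempotent.
- **Probe collapse**: `max_mean_probe` (keep the probe with the largest mean,
  the usual microarray convention) or `gene_mean`.
- **Fold changes**: signed convention, `+2^|Δ|` for Δ ≥ 0 and `−2^|Δ|`
  otherwise, where Δ is the mean paired log2 difference (equivalently the
  ratio of geometric means on the linear scale).

## Moderated t-test

Per gene, with `n` paired differences, sample variance `s²` on `df = n − 1`
degrees of freedom:

```
s²_post = (d0·s0² + df·s²) / (d0 + df)
t       = mean(diff) / sqrt(s²_post / n),   p from t on d0 + df df
```

The prior `(d0, s0²)` is estimated by the method of moments on `e = log s²`
under the scaled-F sampling model:

```
var(e)  = trigamma(df/2) + trigamma(d0/2)
mean(e) = log s0² + [digamma(df/2) − log(df/2)] − [digamma(d0/2) − log(d0/2)]
```

`d0` solves the trigamma equation by bisection on [0.1, 500]; when the
observed `var(e)` does not exceed `trigamma(df/2)` the dispersion is fully
explained by sampling noise and `d0 = ∞` (total shrinkage, normal-tail
p-values). When `var(e)` is numerically zero (< 1e-12, i.e. all variances
identical up to rounding) `s0²` is taken as the common value directly — the
bias-correction terms are meaningless in that degenerate case. Non-positive
variances are excluded from estimation with a logged count. The estimator is
cross-checked in the test suite against an independent R implementation.

Multiple testing uses the Benjamini–Hochberg step-up procedure per contrast
(the three contrasts answer distinct questions and are reported separately;
no across-contrast adjustment is applied). Candidate genes satisfy
|signed fold change| > `fc` (default 2) **and** q < `fdr` (default 0.05),
both strict.

## Signatures, Venn partition, reversal, clustering

The three candidate sets are partitioned into the 7 disjoint regions of a
three-set Venn diagram (`papule_only`, …, `all_three`); region sizes must sum
to the union size and this conservation is asserted at run time. Each
treatment-specific (`trifarotene_only`) gene is classified by the signs of
its papule and trifarotene log2 changes: up-in-papule/down-after-treatment,
the mirror, or `other`. For heatmap ordering, gene profiles restricted to
`L_NI`, `L1`, `R3` are z-scored per gene and clustered by average-linkage
(UPGMA) hierarchical clustering under 1 − Pearson distance; samples are never
clustered; genes are processed in lexicographic order so the result does not
depend on input order.

## Preranked GSEA

Genes are ranked by the moderated t (ties broken lexicographically for
determinism). The enrichment score is the signed extremum of the weighted
Kolmogorov–Smirnov running sum (hit increments `|metric|^w / Σ|metric|^w`,
default weight 1; miss decrements `1/(N − n_hits)`). Significance comes from
random gene sets of the same size drawn from the ranked universe
(`n_perm` = 1000 by default): the p-value is add-one and stratified by ES
sign, and NES divides ES by the mean |null ES| of the same sign. Gene-set
permutation (rather than sample permutation) is chosen because with 9
subjects per arm sample permutations are too few; its known tendency toward
optimism on correlated data is a stated limitation.

## Cell-type marker scoring

A panel score is the arithmetic mean of the log2 values of the panel's
marker genes present in the matrix (absent markers are dropped, never
zero-filled; coverage is always reported). The packaged panels are 11 major
cell-type panels and 4 macrophage-polarization panels (M0, M1, M2, SPP1⁺).
Group comparisons use the two-sided Wilcoxon rank-sum test: exact p by full
enumeration of all C(n_x+n_y, n_x) assignments when n_x+n_y ≤ 12 and there
are no ties (enumeration stays under a second at that size), otherwise a
normal approximation with tie and continuity corrections. Significance stars
follow `* < 0.05`, `** < 0.01`, `*** < 0.0001` by default (an alternative
conventional scale with `*** < 0.001` is provided); no multiplicity
adjustment is applied across panels or pairs, so stars are per-comparison
descriptions, not family-wise claims.

## Synthetic study generator

The generator emulates the paired clinical design; its defaults are the
study conditions (9 subjects × 4 conditions):

```
y[g,s,c] = mu_g + b[g,s] + delta[g,c] + m[g,c] + eps[g,s,c]
```

- `mu_g ~ U(4, 12)`: log2 baselines spanning the array's dynamic range.
- `b[g,s] ~ N(0, subject_sd²)`, default 0.3: a per-gene subject effect that
  cancels exactly in within-subject differences (as in the real design).
- `eps ~ N(0, σ_g²)` with `σ_g²` drawn from a scaled-inverse-χ² prior
  (`var_prior_df` = 4, scale `noise_sd²` with `noise_sd` = 0.4), so the
  empirical-Bayes estimator has a recoverable target; Gaussian noise on log2
  scale matches RMA-normalized intensities and the downstream t-statistics.
- `delta[g,c]` plants differential expression per Venn region: condition
  offsets are `delta(L_NI)=0`, `delta(L1)=e_pap`, `delta(L3)=e_pap+e_veh`,
  `delta(R3)=e_pap+e_tri`, so each region's contrasts carry an effect of
  exactly `effect_log2fc` (default 2.0). Each planted gene draws a lesion
  direction (up with probability 0.8); resolution-contrast effects are
  mirrored, emulating lesion genes whose induction is reversed. Genes planted
  only in resolution contrasts (e.g. `trifarotene_only`) have a papule effect
  of exactly zero, so their expected reversal class is `other`.
- `m[g,c]` adds cell-type panel shifts (panel, condition) → log2 amount;
  planted DE genes are drawn from non-marker features so the two kinds of
  signal never overlap.

The generator **emulates**: the paired structure, heteroscedastic per-gene
noise with a known variance prior, region-structured DE with directional
reversal, and additive marker-panel abundance shifts. It does **not**
emulate: probe-level effects or annotation ambiguity, gene–gene correlation
beyond panel co-shifts, intensity-dependent variance, batch effects, or
missing samples. Consequently quantities that depend on a real dataset's
correlation structure and probe annotation (e.g. any specific published
region counts) are not reproduction targets; the package's claims are the
calibration, recovery and power properties asserted in the test suite and
measured by `scripts/acceptance.py`.

## Numerical choices

- Prior estimation brackets `d0/2` in [0.05, 250] for the trigamma
  inversion and clamps at the bracket edges; `xtol = 1e-10`.
- Degenerate variance cases: `var(log s²) < 1e-12` → common variance;
  `d0 = 0` override → classic t (zero-variance genes get NaN p and are
  excluded from BH with a logged count).
- BH is computed on the finite p-values only; NaNs stay NaN.
- Enrichment running sums use cumulative sums; permutation ES values are
  computed batch-wise for speed; the extremum takes the first index attaining
  the maximal |deviation|.
- All stochastic stages derive per-stage substreams from one config seed via
  `SeedSequence`, masked to < 2^31, so e.g. changing the number of GSEA
  permutations never perturbs the simulated study; pipeline outputs are
  bit-identical under a fixed seed.

## Limitations

- Gene-set permutation GSEA p-values are optimistic under strong inter-gene
  correlation; they are calibrated for independent rankings (verified on
  random sets) but should be read qualitatively on real data.
- The rank-sum comparisons treat samples as independent groups; with paired
  designs and a nonzero subject effect the test is conservative (this is
  visible in the generator and documented in the tests).
- Marker-panel scores are abundance proxies, not proportion estimates; no
  deconvolution is attempted.
- The moderated-t model assumes approximately Gaussian log2 differences and
  exchangeable variances across genes; heavy-tailed contamination will
  inflate `d0` downward.
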