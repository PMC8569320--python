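"""Paired differential expression with empirical-Bayes moderated t-statistics.

A two-condition paired contrast is analysed as a one-sample problem on
within-subject log2 differences, which is exactly the subject-blocked linear
model for that contrast. Per gene the moderated t shrinks the sample variance
s² (df = n−1) toward a prior variance s0² with prior degrees of freedom d0:

    s²_post = (d0·s0² + df·s²) / (d0 + df)
    t_mod   = mean(diff) / sqrt(s²_post / n)

and p-values come from a t distribution on d0 + df degrees of freedom. The
hyperparameters (d0, s0²) are estimated by matching the first two moments of
log s² under the scaled-F sampling model (s² | σ² ~ σ²·χ²_df/df with
1/σ² ~ χ²_d0/(d0·s0²)):

    var(log s²)  = trigamma(df/2) + trigamma(d0/2)
    E[log s²]    = log s0² + [digamma(df/2) − log(df/2)] − [digamma(d0/2) − log(d0/2)]

d0 is solved by inverting the trigamma equation; when the observed dispersion
of log s² does not exceed trigamma(df/2) the log-variances are consistent with
a single common variance and d0 = +inf (total shrinkage). Multiple testing is
adjusted per contrast with the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from acnesig.io_formats import CONDITIONS, ExpressionMatrix, SampleTable
from acnesig.preprocess import signed_fold_change

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    """A two-condition comparison, condition_a minus condition_b."""

    name: str
    condition_a: str
    condition_b: str
    paired: bool = True

    def __post_init__(self) -> None:
        for c in (self.condition_a, self.condition_b):
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}; allowed: {list(CONDITIONS)}")
        if self.condition_a == self.condition_b:
            raise ValueError("contrast conditions must differ")


#: The study's three contrasts of interest.
PAPULE = Contrast("papule", "L1", "L_NI")
VEHICLE = Contrast("vehicle", "L3", "L1")
TRIFAROTENE = Contrast("trifarotene", "R3", "L1")
STUDY_CONTRASTS: tuple[Contrast, ...] = (PAPULE, VEHICLE, TRIFAROTENE)


@dataclass
class ContrastResult:
    """Per-gene moderated-t results for one contrast.

    ``table`` columns: gene, delta_log2 (mean paired difference), signed_fc,
    s2 (residual variance), t_mod, p_raw, q_bh. ``df`` is the residual degrees
    of freedom (n_pairs − 1); ``d0`` and ``s0_sq`` the empirical-Bayes prior.
    """

    name: str
    table: pd.DataFrame
    d0: float
    s0_sq: float
    df: int
    n_pairs: int

    def candidates(self, fc_threshold: float = 2.0, q_threshold: float = 0.05):
        return select_candidates(self, fc_threshold, q_threshold)


def paired_differences(
    m: ExpressionMatrix, samples: SampleTable, contrast: Contrast
) -> pd.DataFrame:
    """Within-subject differences (condition_a − condition_b), genes × subjects.

    Subjects missing either condition are dropped with a logged list; fewer
    than two complete subjects is a hard error.
    """
    condition_of = samples.condition_of()
    subject_of = samples.subject_of()
    by_subject: dict[str, dict[str, str]] = {}
    for s in m.sample_ids:
        if s not in condition_of:
            raise ValueError(f"sample {s!r} not annotated in sample table")
        by_subject.setdefault(subject_of[s], {})[condition_of[s]] = s

    complete = {
        subj: cond_map
        for subj, cond_map in by_subject.items()
        if contrast.condition_a in cond_map and contrast.condition_b in cond_map
    }
    dropped = sorted(set(by_subject) - set(complete))
    if dropped:
        logger.info(
            "contrast %s: dropped incomplete subjects %s", contrast.name, dropped
        )
    if len(complete) < 2:
        raise ValueError(
            f"contrast {contrast.name}: fewer than 2 subjects have both "
            f"{contrast.condition_a} and {contrast.condition_b}"
        )
    subjects = sorted(complete)
    a_cols = [complete[s][contrast.condition_a] for s in subjects]
    b_cols = [complete[s][contrast.condition_b] for s in subjects]
    diffs = m.values[a_cols].to_numpy() - m.values[b_cols].to_numpy()
    return pd.DataFrame(diffs, index=m.feature_ids, columns=subjects)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments estimate of the variance prior (d0, s0²).

    Works on e = log(s²) of the genes with positive sample variance
    (non-positive ones are excluded with a logged count; at least 10 genes
    required). If var(e) ≤ trigamma(df/2) the dispersion is fully explained by
    sampling noise and d0 = +inf with s0² the bias-corrected mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    n_excluded = int((~positive).sum())
    if n_excluded:
        logger.info("estimate_prior: excluded %d non-positive variances", n_excluded)
    s2 = s2[positive]
    if s2.size < 10:
        raise ValueError("estimate_prior needs at least 10 positive variances")

    e = np.log(s2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    tri_df = float(special.polygamma(1, df / 2.0))
    excess = e_var - tri_df

    if e_var < 1e-12:
        # all variances identical (up to rounding): take the common value
        return math.inf, math.exp(e_mean)
    if excess <= 0:
        d0 = math.inf
        log_s0 = e_mean - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
        return d0, math.exp(log_s0)

    def f(d0_):
        return float(special.polygamma(1, d0_ / 2.0)) - excess

    lo, hi = 0.1, 500.0
    if f(lo) <= 0:  # dispersion even larger than trigamma(0.05): clamp at lower edge
        d0 = lo
    elif f(hi) >= 0:  # dispersion tiny: effectively infinite prior df
        d0 = math.inf
    else:
        d0 = float(optimize.brentq(f, lo, hi, xtol=1e-10))

    if math.isinf(d0):
        corr_d0 = 0.0
    else:
        corr_d0 = float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    log_s0 = (
        e_mean
        - (float(special.digamma(df / 2.0)) - math.log(df / 2.0))
        + corr_d0
    )
    return d0, math.exp(log_s0)


def fit_moderated_t(
    diffs: pd.DataFrame, name: str = "contrast", d0: float | None = None
) -> ContrastResult:
    """Empirical-Bayes moderated one-sample t-test on a difference matrix.

    ``d0`` overrides the estimated prior degrees of freedom (``d0=0`` gives
    the classic unmoderated t). Genes with zero sample variance get a finite
    posterior variance through shrinkage when d0 > 0; with d0 = 0 their p is
    NaN and they are excluded from the BH adjustment with a logged count.
    """
    values = diffs.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("fit_moderated_t needs at least 2 paired differences")
    df = n - 1
    beta = values.mean(axis=1)
    s2 = values.var(axis=1, ddof=1)

    if d0 is None:
        if np.all(s2 <= 0):
            raise ValueError(
                "all genes have zero variance across differences; "
                "the data carry no noise to estimate a prior from"
            )
        d0_est, s0_sq = estimate_prior(s2, df)
    else:
        d0_est = float(d0)
        if d0_est > 0:
            # prior scale still estimated from the data when shrinkage is requested
            _, s0_sq = estimate_prior(s2, df) if np.any(s2 > 0) else (d0_est, float("nan"))
        else:
            s0_sq = float("nan")

    if math.isinf(d0_est):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0_est == 0:
        s2_post = s2.copy()
        df_total = float(df)
    else:
        s2_post = (d0_est * s0_sq + df * s2) / (d0_est + df)
        df_total = d0_est + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = beta / np.sqrt(s2_post / n)
    t_mod = np.where(s2_post > 0, t_mod, np.nan)
    n_nan = int(np.isnan(t_mod).sum())
    if n_nan:
        logger.info(
            "fit_moderated_t(%s): %d genes with undefined statistic excluded "
            "from multiple-testing adjustment",
            name,
            n_nan,
        )

    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    q = bh_adjust(p)

    table = pd.DataFrame(
        {
            "gene": diffs.index,
            "delta_log2": beta,
            "signed_fc": signed_fold_change(beta),
            "s2": s2,
            "t_mod": t_mod,
            "p_raw": p,
            "q_bh": q,
        }
    ).set_index("gene", drop=False)
    return ContrastResult(
        name=name, table=table, d0=d0_est, s0_sq=s0_sq, df=df, n_pairs=n
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j ≥ i} m·p_(j)/j over the sorted p-values, capped at 1;
    output order matches input order. NaN entries are excluded from the
    adjustment (m counts only the tested genes) and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    adjusted = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[finite] = out
    return q


def select_candidates(
    result: ContrastResult, fc_threshold: float = 2.0, q_threshold: float = 0.05
) -> dict[str, int]:
    """Candidate DE genes: |signed FC| strictly > threshold and q strictly < threshold.

    Returns gene → direction (+1 up, −1 down). Both comparisons are strict, so
    a gene at exactly fold change 2 is not selected.
    """
    t = result.table
    mask = (t["signed_fc"].abs() > fc_threshold) & (t["q_bh"] < q_threshold)
    signs = np.sign(t.loc[mask, "delta_log2"]).astype(int)
    return dict(zip(t.loc[mask, "gene"], signs))


def run_contrast(
    m: ExpressionMatrix,
    samples: SampleTable,
    contrast: Contrast,
    d0: float | None = None,
) -> ContrastResult:
    """Convenience composition: paired differences then moderated t."""
    diffs = paired_differences(m, samples, contrast)
    return fit_moderated_t(diffs, name=contrast.name, d0=d0)
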