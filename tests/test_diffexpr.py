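"""Moderated t-statistics, prior estimation, BH adjustment, candidate selection."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from acnesig.diffexpr import (
    PAPULE,
    TRIFAROTENE,
    Contrast,
    bh_adjust,
    estimate_prior,
    fit_moderated_t,
    paired_differences,
    run_contrast,
    select_candidates,
)
from acnesig.io_formats import ExpressionMatrix, SampleTable
from acnesig.synthetic import StudyDesignConfig, simulate_study
from tests.conftest import paired_samples


def diff_frame(rng, n_genes=200, n_subjects=9, sd=0.5):
    values = rng.normal(0.0, sd, size=(n_genes, n_subjects))
    return pd.DataFrame(
        values,
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(n_subjects)],
    )


class TestPairedDifferences:
    def test_simple_difference(self, samples9):
        values = pd.DataFrame(5.0, index=["f1"], columns=samples9.sample_ids)
        values.loc["f1", "S00_L1"] = 7.0
        diffs = paired_differences(ExpressionMatrix(values), samples9, PAPULE)
        assert diffs.loc["f1", "S00"] == 2.0
        assert diffs.shape == (1, 9)

    def test_incomplete_subject_dropped(self, samples9):
        keep = [s for s in samples9.sample_ids if s != "S00_L_NI"]
        table = samples9.table[samples9.table["sample_id"].isin(keep)]
        m = ExpressionMatrix(
            pd.DataFrame(5.0, index=["f1"], columns=keep)
        )
        diffs = paired_differences(m, SampleTable(table), PAPULE)
        assert "S00" not in diffs.columns
        assert diffs.shape[1] == 8

    def test_antisymmetry(self, study_matrix, samples9):
        fwd = paired_differences(study_matrix, samples9, PAPULE)
        rev = paired_differences(
            study_matrix, samples9, Contrast("rev", "L_NI", "L1")
        )
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_too_few_subjects_is_error(self):
        samples = paired_samples(1)
        m = ExpressionMatrix(
            pd.DataFrame(5.0, index=["f1"], columns=samples.sample_ids)
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            paired_differences(m, samples, PAPULE)


class TestFitModeratedT:
    def test_d0_zero_equals_classic_t(self, rng):
        diffs = diff_frame(rng)
        result = fit_moderated_t(diffs, d0=0)
        classic = stats.ttest_1samp(diffs.to_numpy(), 0.0, axis=1)
        np.testing.assert_allclose(result.table["t_mod"], classic.statistic, atol=1e-10)
        np.testing.assert_allclose(result.table["p_raw"], classic.pvalue, atol=1e-10)

    def test_homogeneous_variance_fixed_point(self, rng):
        # identical per-gene variances: s0_sq equals that variance and the
        # moderated statistic equals the classic t for every gene
        base = rng.normal(0.0, 1.0, size=9)
        base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, var 1
        shifts = rng.normal(0.0, 2.0, size=50)
        diffs = pd.DataFrame(
            base[None, :] + shifts[:, None],
            index=[f"G{i}" for i in range(50)],
            columns=[f"S{j}" for j in range(9)],
        )
        result = fit_moderated_t(diffs)
        assert result.d0 == np.inf
        assert result.s0_sq == pytest.approx(1.0, rel=1e-9)
        classic = stats.ttest_1samp(diffs.to_numpy(), 0.0, axis=1)
        np.testing.assert_allclose(result.table["t_mod"], classic.statistic, atol=1e-8)

    def test_hyperparameter_recovery_from_simulated_study(self):
        # studies simulated with a known variance prior; the estimates should
        # concentrate near the truth (median over seeds)
        d0s, s0s = [], []
        for seed in range(20):
            cfg = StudyDesignConfig(
                n_genes=5000, noise_sd=0.5, var_prior_df=4.0, subject_sd=0.0, seed=seed
            )
            m, samples, _ = simulate_study(cfg)
            result = run_contrast(m, samples, PAPULE)
            d0s.append(result.d0)
            s0s.append(result.s0_sq)
        # paired differences double the variance: target scale is 2 * 0.25
        assert abs(np.median(d0s) - 4.0) / 4.0 < 0.3
        assert abs(np.median(s0s) - 0.5) / 0.5 < 0.1

    def test_moderation_shrinks_statistic_spread(self, rng):
        # heteroscedastic genes: moderated t has smaller spread than classic t
        sds = rng.uniform(0.1, 2.0, size=300)
        diffs = pd.DataFrame(
            rng.normal(0, 1, size=(300, 9)) * sds[:, None],
            index=[f"G{i}" for i in range(300)],
            columns=[f"S{j}" for j in range(9)],
        )
        moderated = fit_moderated_t(diffs)
        classic = fit_moderated_t(diffs, d0=0)
        assert moderated.table["t_mod"].var() < classic.table["t_mod"].var()

    def test_all_zero_variance_is_error(self):
        diffs = pd.DataFrame(
            np.ones((20, 4)), index=[f"G{i}" for i in range(20)], columns=list("abcd")
        )
        with pytest.raises(ValueError, match="zero variance"):
            fit_moderated_t(diffs)

    def test_antisymmetry_of_contrast_direction(self, study_matrix, samples9):
        fwd = run_contrast(study_matrix, samples9, PAPULE)
        rev = run_contrast(study_matrix, samples9, Contrast("rev", "L_NI", "L1"))
        np.testing.assert_allclose(
            fwd.table["delta_log2"], -rev.table["delta_log2"], atol=1e-12
        )
        np.testing.assert_allclose(fwd.table["t_mod"], -rev.table["t_mod"], atol=1e-10)
        np.testing.assert_allclose(fwd.table["p_raw"], rev.table["p_raw"], atol=1e-12)
        np.testing.assert_allclose(fwd.table["q_bh"], rev.table["q_bh"], atol=1e-12)


class TestEstimatePrior:
    def test_constant_variances_total_shrinkage(self):
        d0, s0_sq = estimate_prior(np.full(100, 0.25), df=8)
        assert d0 == np.inf
        assert s0_sq == pytest.approx(0.25)

    def test_recovery_band_for_known_prior(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sigma2 = 10.0 * 0.25 / rng.chisquare(10.0, 10000)
            s2 = sigma2 * rng.chisquare(8, 10000) / 8
            d0, _ = estimate_prior(s2, df=8)
            hits += 6.0 <= d0 <= 16.0
        assert hits >= 19

    def test_mixed_populations_partial_shrinkage(self, rng):
        s2 = np.concatenate([rng.chisquare(8, 500) / 8 * 0.1,
                             rng.chisquare(8, 500) / 8 * 2.0])
        d0, s0_sq = estimate_prior(s2, df=8)
        assert np.isfinite(d0) and d0 > 0
        # posterior variance lies strictly between s2 and s0_sq genewise
        s2_post = (d0 * s0_sq + 8 * s2) / (d0 + 8)
        between = ((s2_post > np.minimum(s2, s0_sq)) &
                   (s2_post < np.maximum(s2, s0_sq)))
        assert between.all()

    def test_matches_limma_reference(self, tmp_path):
        # independent oracle: limma's moment estimator on the same draws
        rng = np.random.default_rng(42)
        sigma2 = 10.0 * 0.25 / rng.chisquare(10.0, 2000)
        s2 = sigma2 * rng.chisquare(8, 2000) / 8
        s2_file = tmp_path / "s2.tsv"
        np.savetxt(s2_file, s2)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"s2 <- scan('{s2_file}')\n"
            "f <- fitFDist(s2, df1=8)\n"
            "cat(f$df2, f$scale, sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref_d0, ref_s0 = (float(x) for x in out.stdout.split())
        d0, s0_sq = estimate_prior(s2, df=8)
        assert d0 == pytest.approx(ref_d0, rel=1e-6)
        assert s0_sq == pytest.approx(ref_s0, rel=1e-6)


class TestBhAdjust:
    def test_hand_run_step_up(self):
        q = bh_adjust(np.array([0.01, 0.04, 0.03, 0.05]))
        np.testing.assert_allclose(q, [0.04, 0.05, 0.05, 0.05])

    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust(np.array([1.0])), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(0, 1, size=rng.integers(1, 50))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(0, 1, size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15)


class TestSelectCandidates:
    def _result(self, deltas, qs):
        from acnesig.diffexpr import ContrastResult
        from acnesig.preprocess import signed_fold_change

        genes = [f"g{i}" for i in range(len(deltas))]
        table = pd.DataFrame(
            {
                "gene": genes,
                "delta_log2": deltas,
                "signed_fc": signed_fold_change(np.asarray(deltas)),
                "s2": 1.0,
                "t_mod": 0.0,
                "p_raw": qs,
                "q_bh": qs,
            }
        ).set_index("gene", drop=False)
        return ContrastResult("test", table, 4.0, 1.0, 8, 9)

    def test_boundary_fold_change_excluded(self):
        result = self._result([1.0], [0.01])  # signed_fc exactly 2.0
        assert select_candidates(result) == {}

    def test_strongly_down_gene_selected(self):
        # a gene at FC −28.2, q 0.0022 is a candidate with direction down
        result = self._result([-np.log2(28.2)], [0.0022])
        assert select_candidates(result) == {"g0": -1}

    def test_matches_brute_force_filter(self, rng):
        deltas = rng.normal(0, 2, size=200)
        qs = rng.uniform(0, 0.2, size=200)
        result = self._result(deltas, qs)
        got = select_candidates(result, 2.0, 0.05)
        expected = {}
        for gene, row in result.table.iterrows():
            if abs(row["signed_fc"]) > 2.0 and row["q_bh"] < 0.05:
                expected[gene] = 1 if row["delta_log2"] > 0 else -1
        assert got == expected


class TestNullCalibration:
    def test_type_one_error_and_fdr_control(self):
        from acnesig.synthetic import simulate_null_study

        rates, q_counts = [], []
        for seed in range(5):
            m, samples = simulate_null_study(9, 1500, seed=100 + seed)
            for contrast in (PAPULE, TRIFAROTENE):
                r = run_contrast(m, samples, contrast)
                rates.append((r.table["p_raw"] < 0.05).mean())
                q_counts.append((r.table["q_bh"] < 0.05).sum())
        assert 0.03 <= np.mean(rates) <= 0.07
        assert np.mean(q_counts) < 1
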