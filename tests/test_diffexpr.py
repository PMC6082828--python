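"""Linear models, variance moderation, BH and fixed-effect meta-analysis."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smokesig.diffexpr import (
    DesignSpec,
    adjust_bh,
    derive_signature,
    differential_expression,
    estimate_prior,
    fit_gene_models,
    meta_analyze_fixed,
    moderate_variances,
    posterior_variances,
)
from smokesig.synthetic import StudyConfig, generate_expression_study
from helpers import bh_bruteforce, make_study


class TestFitGeneModels:
    def test_constant_groups_exact_logfc(self):
        study = make_study([[1, 1, 1, 3, 3, 3]], ["control"] * 3 + ["exposed"] * 3)
        fit = fit_gene_models(study, DesignSpec())
        assert fit["logFC"].iloc[0] == pytest.approx(2.0)
        assert fit["sigma2"].iloc[0] == pytest.approx(0.0)

    def test_identical_groups_zero_logfc(self):
        study = make_study([[5, 5, 5, 5]], ["exposed", "exposed", "control", "control"])
        assert fit_gene_models(study, DesignSpec())["logFC"].iloc[0] == pytest.approx(0.0)

    def test_residual_df_is_n_minus_p(self, two_group_study):
        fit = fit_gene_models(two_group_study, DesignSpec())
        assert (fit["df"] == 12 - 2).all()
        three_three = make_study(
            np.arange(12.0).reshape(2, 6), ["exposed"] * 3 + ["control"] * 3
        )
        assert (fit_gene_models(three_three, DesignSpec())["df"] == 4).all()

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 10
        study = make_study(rng.normal(size=(5, n)), ["exposed"] * 5 + ["control"] * 5)
        study.samples["age"] = rng.integers(40, 70, size=n)
        design = DesignSpec(covariates=("age",))
        fit = fit_gene_models(study, design)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "group": (study.samples["group"] == "exposed").astype(float),
                    "age": study.samples["age"].astype(float),
                }
            )
        )
        for i, gene in enumerate(study.genes):
            res = sm.OLS(study.values.loc[gene].to_numpy(), X.to_numpy()).fit()
            assert fit["logFC"].iloc[i] == pytest.approx(res.params[1])
            assert fit["SE"].iloc[i] == pytest.approx(res.bse[1])

    def test_rank_deficient_design_names_columns(self, rng):
        study = make_study(rng.normal(size=(3, 6)), ["exposed"] * 3 + ["control"] * 3)
        study.samples["dup"] = (study.samples["group"] == "exposed").astype(float)
        with pytest.raises(ValueError, match="dup"):
            fit_gene_models(study, DesignSpec(covariates=("dup",)))

    def test_level_and_count_validation(self, rng):
        study = make_study(rng.normal(size=(2, 3)), ["exposed", "exposed", "control"])
        with pytest.raises(ValueError, match="at least 2"):
            fit_gene_models(study, DesignSpec())


class TestModeration:
    def test_shrinkage_formula_arithmetic(self):
        # (d0*s0^2 + df*s^2)/(d0 + df) = (4*1 + 4*2)/8 = 1.5
        assert posterior_variances(np.array([2.0]), 4.0, d0=4.0, s02=1.0)[0] == pytest.approx(1.5)

    def test_infinite_prior_df_collapses_to_prior(self, rng):
        s2 = rng.chisquare(4, size=50) / 4
        mod = moderate_variances(s2, 4.0, prior=(np.inf, 1.3))
        assert np.allclose(mod.s2_post, 1.3)

    def test_zero_prior_df_no_shrinkage(self, rng):
        s2 = rng.chisquare(4, size=50) / 4
        mod = moderate_variances(s2, 4.0, prior=(0.0, 1.0))
        assert np.allclose(mod.s2_post, s2)

    def test_equal_variances_give_infinite_d0(self):
        mod = moderate_variances(np.full(100, 2.0), 4.0)
        assert np.isinf(mod.d0)
        assert np.allclose(mod.s2_post, mod.s02)

    def test_prior_recovery_from_scaled_inv_chisq(self, rng):
        # s_g^2 ~ sigma_g^2 * chi2_df/df with sigma_g^2 ~ d0*s02/chi2_d0:
        # moment estimation recovers d0 within 25% and s02 within 10%
        d0_true, s02_true, df, n = 8.0, 0.6, 4.0, 5000
        sigma2 = d0_true * s02_true / rng.chisquare(d0_true, size=n)
        s2 = sigma2 * rng.chisquare(df, size=n) / df
        d0, s02 = estimate_prior(s2, df)
        assert abs(d0 - d0_true) / d0_true < 0.25
        assert abs(s02 - s02_true) / s02_true < 0.10

    def test_moderated_t_null_pvalues_uniform(self, rng):
        study_cfg = StudyConfig(n_genes=800, n_exposed=8, n_control=8, frac_de=0.0, seed=12)
        study, _ = generate_expression_study(study_cfg)
        table = differential_expression(study, DesignSpec())
        assert stats.kstest(table["p_value"], "uniform").pvalue > 1e-3

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_limma_on_small_fixture(self, rng, tmp_path):
        # independent oracle: limma::eBayes on the same per-gene fits
        study = make_study(
            rng.normal(7, 0.6, size=(60, 10)), ["exposed"] * 5 + ["control"] * 5
        )
        study.values.iloc[:6, :5] += 1.5
        study.values.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("expr.tsv", row.names = 1))
            design <- cbind(1, c(rep(1, 5), rep(0, 5)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(d0 = fit$df.prior, s02 = fit$s2.prior,
                              t = fit$t[, 2], p = fit$p.value[, 2])
            write.table(out, "limma.tsv", sep = "\t", quote = FALSE)
            """
        )
        (tmp_path / "run.R").write_text(script)
        subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, check=True,
            capture_output=True, timeout=120,
        )
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        table = differential_expression(study, DesignSpec()).set_index("gene").loc[study.genes]
        mod = moderate_variances(
            fit_gene_models(study, DesignSpec())["sigma2"].to_numpy(), 8.0
        )
        assert mod.d0 == pytest.approx(ref["d0"].iloc[0], rel=0.05)
        assert mod.s02 == pytest.approx(ref["s02"].iloc[0], rel=0.05)
        assert np.allclose(table["t"].to_numpy(), ref["t"].to_numpy(), rtol=5e-3)
        assert np.allclose(table["p_value"].to_numpy(), ref["p"].to_numpy(), rtol=5e-3)


class TestAdjustBh:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.005, 0.5], [0.01, 0.5]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert np.allclose(adjust_bh(np.array(p)), expected)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(adjust_bh(np.array(p)), bh_bruteforce(p))

    def test_nan_propagated_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = adjust_bh(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], [0.02, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]))


class TestMetaAnalyzeFixed:
    def test_single_cohort_unchanged(self):
        res = meta_analyze_fixed(np.array([[1.7]]), np.array([[0.4]]))
        assert res.effect[0] == pytest.approx(1.7)
        assert res.se[0] == pytest.approx(0.4)

    def test_equal_se_closed_form(self):
        res = meta_analyze_fixed(np.array([[1.0, 3.0]]), np.array([[1.0, 1.0]]))
        assert res.effect[0] == pytest.approx(2.0)
        assert res.se[0] == pytest.approx(0.7071, abs=1e-4)

    def test_unequal_se_closed_form(self):
        res = meta_analyze_fixed(np.array([[1.0, 1.0]]), np.array([[1.0, 2.0]]))
        assert res.effect[0] == pytest.approx(1.0)
        assert res.se[0] == pytest.approx(1 / np.sqrt(1.25))

    def test_equal_ses_reduce_to_arithmetic_mean(self, rng):
        b = rng.normal(size=(30, 4))
        res = meta_analyze_fixed(b, np.full_like(b, 0.3))
        assert np.allclose(res.effect, b.mean(axis=1))

    def test_combined_se_below_every_cohort_se(self, rng):
        b = rng.normal(size=(20, 3))
        s = rng.uniform(0.1, 2.0, size=(20, 3))
        res = meta_analyze_fixed(b, s)
        assert (res.se <= s.min(axis=1) + 1e-12).all()

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            meta_analyze_fixed(np.array([[1.0, 2.0]]), np.array([[0.0, 1.0]]))


class TestDeriveSignature:
    def _table(self, rng, n=100):
        study, truth = generate_expression_study(
            StudyConfig(n_genes=500, n_exposed=24, n_control=24, frac_de=0.1,
                        effect_mean=2.0, effect_sd=0.0, noise_sd=0.5, seed=13)
        )
        return differential_expression(study, DesignSpec()), truth

    def test_cutoff_one_keeps_all_genes(self, rng):
        table, _ = self._table(rng)
        sig = derive_signature(table, 1.0, species="mouse")
        assert len(sig) == len(table)

    def test_nested_cutoffs(self, rng):
        table, _ = self._table(rng)
        s01 = derive_signature(table, 0.01).genes
        s05 = derive_signature(table, 0.05).genes
        s10 = derive_signature(table, 0.10).genes
        assert s01 <= s05 <= s10

    def test_planted_recovery_at_10pct_fdr(self, rng):
        # effect 2.0, noise 0.5, 24+24 samples: >= 90% sensitivity, FDP <= 0.15
        table, truth = self._table(rng)
        sig = derive_signature(table, 0.1, species="mouse")
        planted = set(truth.index[truth["logfc"] != 0])
        called = sig.genes
        sensitivity = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(1, len(called))
        assert sensitivity >= 0.90
        assert fdp <= 0.15

    def test_directions_match_planted_sign(self, rng):
        table, truth = self._table(rng)
        sig = derive_signature(table, 0.1, species="mouse")
        planted = truth[truth["logfc"] != 0]
        hits = sig.entries.index.intersection(planted.index)
        assert (sig.entries.loc[hits, "direction"] == planted.loc[hits, "direction"]).all()

    def test_empty_signature_warns(self):
        table = pd.DataFrame(
            {"gene": ["a", "b"], "logFC": [0.1, -0.2], "SE": 1.0, "t": 0.1,
             "p_value": [0.9, 0.8], "fdr": [0.9, 0.9]}
        )
        with pytest.warns(UserWarning, match="empty"):
            sig = derive_signature(table, 0.1)
        assert len(sig) == 0
        assert sig.universe == {"a", "b"}
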