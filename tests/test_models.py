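"""Mixed-model stage: F tests, LRT, contrasts, effect sizes, VIF, QQ."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import groomnet as gn


@pytest.fixture(scope="module")
def fitted(index_table):
    return gn.fit_lmm(index_table, gn.ModelSpec("gai"))


class TestFitting:
    def test_f_is_squared_t_of_contrast(self, fitted):
        merged = fitted.anova_table.merge(fitted.contrasts, on="factor")
        assert np.allclose(merged["F"], merged["t"] ** 2)

    def test_ols_agreement_with_zero_random_variance(self, index_table):
        import statsmodels.api as sm

        res = gn.fit_lmm(index_table, gn.ModelSpec("gai"), zero_random_variance=True)
        y, X, _, _ = gn.encode_design(index_table, gn.ModelSpec("gai"))
        ols = sm.OLS(y, X).fit()
        for k, f in enumerate(gn.FACTORS, start=1):
            row = res.anova_table[res.anova_table["factor"] == f].iloc[0]
            assert row["F"] == pytest.approx(ols.tvalues.iloc[k] ** 2)
            assert row["p"] == pytest.approx(ols.pvalues.iloc[k])
            assert row["df_den"] == ols.df_resid

    def test_permutation_invariance(self, index_table, fitted):
        shuffled = index_table.sample(frac=1.0, random_state=33).reset_index(drop=True)
        res2 = gn.fit_lmm(shuffled, gn.ModelSpec("gai"))
        pd.testing.assert_frame_equal(
            fitted.anova_table, res2.anova_table, check_exact=False, rtol=1e-4
        )
        assert fitted.tau2 == pytest.approx(res2.tau2, rel=1e-4, abs=1e-10)

    def test_constant_response_flagged_not_crashed(self, index_table):
        degenerate = index_table.assign(gai=0.5)
        res = gn.fit_lmm(degenerate, gn.ModelSpec("gai"))
        assert res.degenerate
        assert not res.converged
        assert "zero residual variance" in res.message
        assert res.anova_table is None

    def test_missing_responses_dropped_with_count(self, index_table):
        holed = index_table.copy()
        holed.loc[holed.index[:4], "gai"] = np.nan
        res = gn.fit_lmm(holed, gn.ModelSpec("gai"))
        assert res.n_dropped == 4
        assert res.n_used == 30

    def test_df_pattern_between_vs_within(self, index_table):
        # repeated measures: between-subject factors (sex, origin) get few
        # denominator df, within-subject factors (season etc.) get many
        res = gn.fit_lmm(index_table, gn.ModelSpec("vsc"))
        df = dict(zip(res.anova_table["factor"], res.anova_table["df_den"]))
        assert df["sex"] < 12 and df["origin"] < 12
        assert df["seasonality"] > 20 and df["group_size"] > 20
        assert df["sex"] < df["seasonality"]


class TestLRT:
    def test_lambda_nonnegative_and_df(self, index_table):
        lrt = gn.compare_full_null(index_table, gn.ModelSpec("gai"))
        assert lrt.statistic >= 0
        assert lrt.df == 5
        assert 0 <= lrt.p <= 1

    def test_strong_effects_give_tiny_p(self, index_table):
        # the session fixture carries the default injected effects
        lrt = gn.compare_full_null(index_table, gn.ModelSpec("gai"))
        assert lrt.p < 0.01


class TestContrasts:
    def test_single_row_per_binary_factor(self, fitted):
        table = gn.posthoc_contrasts(fitted, "seasonality")
        assert len(table) == 1
        assert table.iloc[0]["levels"] == "cold - warm"

    def test_bonferroni_is_capped_family_times_raw(self, fitted):
        for _, row in fitted.contrasts.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 5 * row["p_raw"]))
            assert row["p_bonferroni"] >= row["p_raw"]

    def test_unknown_factor_rejected(self, fitted):
        with pytest.raises(KeyError):
            gn.posthoc_contrasts(fitted, "moon_phase")

    def test_difference_equals_marginal_mean_difference(self, index_table, fitted):
        # brute-force oracle: predictions over the full factor grid, averaged
        # at each level of the target factor
        import itertools

        beta = fitted.coefficients.set_index("term")["estimate"]
        for factor in gn.FACTORS:
            grid = pd.DataFrame(
                list(itertools.product([0, 1], repeat=5)), columns=list(gn.FACTORS)
            )
            pred = beta["const"] + sum(grid[f] * beta[f] for f in gn.FACTORS)
            diff = pred[grid[factor] == 1].mean() - pred[grid[factor] == 0].mean()
            got = gn.posthoc_contrasts(fitted, factor).iloc[0]["difference"]
            assert got == pytest.approx(diff)


class TestCohensD:
    def test_zero_pooled_sd_undefined(self):
        d = gn.reconstruct_design().assign(gai=1.25)
        assert gn.cohens_d(d, "gai", "seasonality") is None

    def test_identical_level_means_give_zero(self):
        d = gn.reconstruct_design()
        # response depends only on season-balanced individual identity
        d = d.assign(gai=d["individual"].map(lambda i: float(ord(i[0]))))
        assert gn.cohens_d(d, "gai", "seasonality") == pytest.approx(0.0)

    def test_separated_groups_give_large_d(self):
        rng = np.random.default_rng(1)
        d = gn.reconstruct_design()
        d = d.assign(gai=np.where(d["season"] == "cold", 1.0, 0.0) + rng.normal(0, 1e-3, len(d)))
        assert abs(gn.cohens_d(d, "gai", "seasonality")) > 100

    def test_random_table_matches_textbook_formula(self):
        rng = np.random.default_rng(42)
        d = gn.reconstruct_design().assign(vsc=rng.gamma(2.0, 1.5, 34))
        got = gn.cohens_d(d, "vsc", "origin")
        a = d.loc[d["origin"] == "wild_caught", "vsc"].to_numpy()
        b = d.loc[d["origin"] == "captive_born", "vsc"].to_numpy()
        sp = np.sqrt(((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
                     / (len(a) + len(b) - 2))
        assert got == pytest.approx((np.mean(a) - np.mean(b)) / sp)


class TestVIF:
    def test_balanced_season_is_exactly_one(self):
        v = gn.vif(gn.reconstruct_design())
        assert v["seasonality"] == pytest.approx(1.0)
        assert (v >= 1.0 - 1e-12).all()

    def test_duplicated_factor_reported_infinite(self):
        d = gn.reconstruct_design()
        # make sex a copy of origin: perfect collinearity
        d["sex"] = np.where(d["origin"] == "wild_caught", "F", "M")
        v = gn.vif(d, ["sex", "origin"])
        assert np.isinf(v["sex"]) and np.isinf(v["origin"])

    def test_matches_independent_matrix_algebra(self):
        d = gn.reconstruct_design()
        v = gn.vif(d)
        # oracle: VIF are the diagonal of the inverse correlation matrix
        X = np.column_stack([
            (d[gn.FACTOR_CODING[f][0]] == gn.FACTOR_CODING[f][2]).astype(float)
            for f in gn.FACTORS
        ])
        R = np.corrcoef(X, rowvar=False)
        expected = np.diag(np.linalg.inv(R))
        for k, f in enumerate(gn.FACTORS):
            assert v[f] == pytest.approx(expected[k])

    def test_model_based_vif_shrinks_with_icc(self):
        d = gn.reconstruct_design()
        groups = d["individual"].to_numpy()
        v0 = gn.model_based_vif(d, gn.FACTORS, groups, tau2=0.0, sigma2=1.0)
        v1 = gn.model_based_vif(d, gn.FACTORS, groups, tau2=1.0, sigma2=1.0)
        assert v0["sex_ratio"] == pytest.approx(gn.vif(d)["sex_ratio"])
        assert v1["sex_ratio"] < v0["sex_ratio"]
        assert v1["seasonality"] == pytest.approx(1.0)


class TestQQ:
    def test_normal_residuals_high_correlation(self):
        rng = np.random.default_rng(3)
        qq = gn.qq_diagnostic(rng.normal(size=200))
        assert qq.correlation > 0.99

    def test_heavy_tails_visibly_lower(self):
        rng = np.random.default_rng(3)
        qq_norm = gn.qq_diagnostic(rng.normal(size=200))
        qq_t2 = gn.qq_diagnostic(rng.standard_t(df=1.5, size=200))
        assert qq_t2.correlation < qq_norm.correlation - 0.02

    def test_pair_count_matches_input(self):
        rng = np.random.default_rng(4)
        qq = gn.qq_diagnostic(rng.normal(size=57))
        assert qq.pairs.shape == (57, 2)


class TestAgainstLme4:
    def test_satterthwaite_matches_lmerTest(self, index_table, tmp_path):
        """Independent oracle: lme4 + lmerTest on the identical dataset."""
        spec = gn.ModelSpec("vsc")
        y, X, groups, _ = gn.encode_design(index_table, spec)
        csv = tmp_path / "d.csv"
        X.drop(columns="const").assign(y=y, id=groups).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            m <- lmer(y ~ group_size + sex_ratio + seasonality + sex + origin + (1|id), data=d)
            a <- anova(m)
            v <- as.data.frame(VarCorr(m))$vcov
            cat(sprintf("%s %.6f %.4f\\n", rownames(a), a$`F value`, a$DenDF))
            cat(sprintf("var %.8f %.8f\\n", v[1], v[2]))
        """)
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        ).stdout
        ours = gn.fit_lmm(index_table, spec)
        lines = [l.split() for l in out.strip().splitlines()]
        r_var = [float(x) for x in lines[-1][1:]]
        assert ours.tau2 == pytest.approx(r_var[0], rel=1e-3, abs=1e-8)
        assert ours.sigma2 == pytest.approx(r_var[1], rel=1e-3)
        r_stats = {l[0]: (float(l[1]), float(l[2])) for l in lines[:-1]}
        for _, row in ours.anova_table.iterrows():
            f_r, df_r = r_stats[row["factor"]]
            assert row["F"] == pytest.approx(f_r, rel=0.01), row["factor"]
            assert row["df_den"] == pytest.approx(df_r, abs=1.0), row["factor"]

    def test_lrt_matches_lme4_ml_comparison(self, index_table, tmp_path):
        spec = gn.ModelSpec("gai")
        y, X, groups, _ = gn.encode_design(index_table, spec)
        csv = tmp_path / "d2.csv"
        X.drop(columns="const").assign(y=y, id=groups).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            mf <- lmer(y ~ group_size + sex_ratio + seasonality + sex + origin + (1|id), data=d, REML=FALSE)
            m0 <- lmer(y ~ (1|id), data=d, REML=FALSE)
            cat(sprintf("%.6f\\n", as.numeric(2*(logLik(mf) - logLik(m0)))))
        """)
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        ).stdout
        lrt = gn.compare_full_null(index_table, spec)
        assert lrt.statistic == pytest.approx(float(out.strip()), abs=0.02)
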