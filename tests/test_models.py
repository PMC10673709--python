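"""Mixed-model structure, LRT deletion tests, Nakagawa R2, gene-GHG models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from droughtflux import models


def make_factorial(rng, n_reps=6, unit_sd=1.0, resid_sd=1.0, drought_eff=0.5, day_eff=1.0):
    """Balanced 4 x 2 x 2 x 2 factorial with a unit random intercept."""
    rows, u = [], 0
    for veg, warm in itertools.product(("wet", "heath", "tussock", "alpine"), ("ambient", "warmed")):
        for _ in range(n_reps):
            b_u = rng.normal(0, unit_sd)
            u += 1
            for drought in ("control", "drought"):
                for day in ("d0", "d56"):
                    y = (
                        1.0
                        + (drought_eff if drought == "drought" else 0.0)
                        + (day_eff if day == "d56" else 0.0)
                        + b_u
                        + rng.normal(0, resid_sd)
                    )
                    rows.append(
                        dict(unit_id=f"u{u}", warming=warm, vegetation_type=veg,
                             drought=drought, harvest_day_f=day, y=y)
                    )
    return pd.DataFrame(rows)


FACTORS = ("harvest_day_f", "vegetation_type", "warming", "drought")


class TestBuildSpec:
    def test_term_counts_for_four_factors(self):
        spec = models.build_spec("y", FACTORS)
        terms = spec.rhs_terms
        assert sum(t.count(":") == 0 for t in terms) == 4
        assert sum(t.count(":") == 1 for t in terms) == 6
        assert sum(t.count(":") == 2 for t in terms) == 4
        assert not any(t.count(":") == 3 for t in terms)  # no four-way terms

    def test_single_factor_main_effect_only(self):
        spec = models.build_spec("y", ("drought",))
        assert spec.rhs_terms == ["drought"]

    def test_time_vegetation_warming_term_present(self):
        # the CH4 model reports a timepoint x vegetation x warming interaction
        spec = models.build_spec("y", FACTORS)
        assert "harvest_day_f:vegetation_type:warming" in spec.rhs_terms

    def test_unknown_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0], "drought": ["control"]})
        with pytest.raises(ValueError, match="unknown model columns"):
            models.build_spec("y", ("drought", "nonexistent"), data=df)


class TestFitLmm:
    def test_no_random_equals_ols(self, rng):
        import patsy
        import statsmodels.api as sm

        df = make_factorial(rng)
        spec = models.build_spec("y", FACTORS, data=df)
        fit = models.fit_lmm(spec, df, random=())
        y, X = patsy.dmatrices(spec.formula, df, return_type="dataframe")
        ref = sm.OLS(np.asarray(y).ravel(), X).fit()
        assert np.allclose(fit.params.to_numpy(), ref.params.to_numpy())
        assert fit.var_group == fit.var_pair == 0.0

    def test_balanced_zero_noise_predictions_equal_group_means(self, rng):
        df = make_factorial(rng, unit_sd=0.0, resid_sd=0.0)
        spec = models.build_spec("y", FACTORS, data=df)
        fit = models.fit_lmm(spec, df, random=())
        df = df.assign(pred=fit.fitted_fixed)
        for _, grp in df.groupby(list(FACTORS)):
            assert np.allclose(grp["pred"], grp["y"].mean(), atol=1e-8)

    def test_residual_df_matches_n_minus_rank(self, rng):
        df = make_factorial(rng)
        spec = models.build_spec("y", FACTORS, data=df)
        fit = models.fit_lmm(spec, df)
        assert fit.df_resid == len(df) - fit.rank == 163

    def test_singular_design_reports_aliased_terms(self, rng):
        df = make_factorial(rng)
        df["warming"] = df["vegetation_type"]  # perfectly confounded
        spec = models.build_spec("y", ("vegetation_type", "warming"), data=df)
        with pytest.raises(models.SingularDesignError, match="aliased"):
            models.fit_lmm(spec, df)

    def test_variance_component_recovery_simulation(self):
        from droughtflux import recovery

        out = recovery.variance_component_recovery(
            n_reps=60, n_units=40, n_per_unit=5, var_unit=1.0, var_resid=1.0, base_seed=5
        )
        assert out["mean_var_unit"] == pytest.approx(1.0, abs=0.2)
        assert out["mean_var_resid"] == pytest.approx(1.0, abs=0.1)


class TestLrt:
    def test_identical_models_stat_zero_p_one(self, rng):
        df = make_factorial(rng)
        spec = models.build_spec("y", ("drought",), data=df)
        stat, lrt_df, p = models.lrt_from_loglik(-50.0, -50.0, 1)
        assert stat == 0.0 and p == 1.0

    def test_fixture_logliks_give_chi_square_p(self):
        stat, lrt_df, p = models.lrt_from_loglik(-100.0, -103.0, 1)
        assert stat == pytest.approx(6.0)
        assert p == pytest.approx(0.014305878435429641, rel=1e-10)

    def test_statistic_floored_at_zero(self):
        stat, _, p = models.lrt_from_loglik(-103.0, -100.0, 1)
        assert stat == 0.0 and p == 1.0

    def test_non_nested_pair_rejected(self, rng):
        df = make_factorial(rng, n_reps=3)
        spec = models.build_spec("y", ("drought",), data=df)
        ols = models.fit_lmm(spec, df, random=(), reml=False)
        with pytest.raises(ValueError, match="nest"):
            models.lrt_random(ols, ols)

    def test_null_variance_component_rarely_rejected(self):
        # dropping a truly-zero variance component: rejection <= nominal level
        rejections = 0
        n_seeds = 40
        spec = models.MixedModelSpec(response="y", factors=("drought",))
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            df = make_factorial(rng, n_reps=3, unit_sd=0.0)
            full = models.fit_lmm(spec, df, random=("pair",), reml=False)
            red = models.fit_lmm(spec, df, random=(), reml=False)
            _, _, p = models.lrt_random(full, red)
            rejections += p <= 0.05
        # the boundary null makes the test conservative; allow small MC slack
        assert rejections / n_seeds <= 0.05 + 0.05


class TestR2:
    def test_direct_arithmetic(self):
        assert models.r2_from_components(3.0, 1.0, 1.0) == pytest.approx((0.6, 0.8))

    def test_zero_fixed_variance_gives_zero_marginal(self):
        r2m, r2c = models.r2_from_components(0.0, 1.0, 1.0)
        assert r2m == 0.0

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            models.r2_from_components(0.0, 0.0, 0.0)

    def test_marginal_equals_conditional_without_random_effects(self, rng):
        df = make_factorial(rng)
        spec = models.build_spec("y", FACTORS, data=df)
        fit = models.fit_lmm(spec, df, random=())
        r2m, r2c = models.r2_nakagawa(fit)
        assert r2m == r2c

    def test_marginal_le_conditional_with_random_effects(self, rng):
        df = make_factorial(rng)
        spec = models.build_spec("y", FACTORS, data=df)
        fit = models.fit_lmm(spec, df)
        r2m, r2c = models.r2_nakagawa(fit)
        assert 0.0 <= r2m <= r2c <= 1.0


class TestGeneGhgModels:
    @staticmethod
    def _day56_data(rng, beta=0.8, n_reps=6):
        rows, u = [], 0
        for veg, warm in itertools.product(("wet", "heath", "tussock", "alpine"), ("ambient", "warmed")):
            for _ in range(n_reps):
                u += 1
                for drought in ("control", "drought"):
                    log_gene = rng.uniform(-3.5, -1.5)
                    rows.append(
                        dict(unit_id=f"u{u}", warming=warm, vegetation_type=veg, drought=drought,
                             ratio_pmoA=10.0**log_gene, ratio_nosZII=10.0 ** rng.uniform(-4, -2),
                             ratio_acdS=10.0 ** rng.uniform(-5, -3),
                             abund_16S=10.0 ** rng.uniform(8, 10), abund_ITS=10.0 ** rng.uniform(7, 9),
                             flux_CO2=beta * log_gene + rng.normal(0, 0.05),
                             flux_CH4=rng.normal(0, 0.01), flux_N2O=rng.normal(0, 0.001))
                    )
        return pd.DataFrame(rows)

    def test_one_model_per_gene(self, rng):
        df = self._day56_data(rng)
        fits = models.fit_gene_ghg_models(df, "flux_CO2")
        assert len(fits) == 4

    def test_n2o_uses_noszii_not_pmoa(self):
        assert "ratio_nosZII" in models.GHG_GENE_SETS["flux_N2O"]
        assert "ratio_pmoA" not in models.GHG_GENE_SETS["flux_N2O"]
        assert "ratio_pmoA" in models.GHG_GENE_SETS["flux_CO2"]

    def test_injected_gene_flux_slope_recovered(self, rng):
        beta = 0.8
        df = self._day56_data(rng, beta=beta)
        fit, _ = models.fit_gene_ghg_models(df, "flux_CO2", gene_list=("ratio_pmoA",))["ratio_pmoA"]
        coef = fit.params["log10_ratio_pmoA"]
        se = np.sqrt(fit.cov_params.loc["log10_ratio_pmoA", "log10_ratio_pmoA"])
        assert abs(coef - beta) < 3 * se

    def test_missing_gene_column_rejected(self, rng):
        df = self._day56_data(rng)
        with pytest.raises(ValueError, match="missing gene column"):
            models.fit_gene_ghg_models(df, "flux_CO2", gene_list=("ratio_missing",))


def test_tukey_contract_returns_pairwise_table(rng):
    df = make_factorial(rng, n_reps=4)
    out = models.tukey_hsd(df, "y", "vegetation_type")
    assert len(out) == 6  # C(4,2) pairwise contrasts
    assert {"group1", "group2", "reject"} <= set(out.columns)
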