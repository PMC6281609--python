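"""Trait derivation and mixed-model residualization."""

import numpy as np
import pandas as pd
import pytest

from qtgtest import (CrossDesign, MediationModel, ModelSpec, adjust_trait,
                     derive_traits, select_fixed_effects,
                     simulate_f2_intercross)
from qtgtest.adjust import DegenerateDesignError

import statsmodels.formula.api as smf


def toy_cohort(rng, n_litters=30, litter_size=8, sigma_litter=1.0,
               sigma_e=1.0, litter_size_beta=0.0, parity_beta=0.0,
               bw_beta=0.0):
    n = n_litters * litter_size
    litter = np.repeat(np.arange(n_litters), litter_size)
    sizes = rng.integers(4, 11, size=n_litters)
    parity = rng.choice([1, 2, 3], size=n_litters)
    bw = rng.normal(30, 3, size=n)
    y = (sigma_litter * rng.normal(size=n_litters)[litter]
         + litter_size_beta * sizes[litter]
         + parity_beta * parity[litter]
         + bw_beta * bw
         + sigma_e * rng.normal(size=n))
    return pd.DataFrame({"litter_id": litter + 1,
                         "litter_size": sizes[litter],
                         "parity": parity[litter],
                         "bw_wk16": bw, "y": y})


class TestDeriveTraits:
    def test_total_fat_is_sum_of_three_pads(self):
        df = pd.DataFrame({"inguinal_fat": [2.416], "gonadal_fat": [1.860],
                           "perirenal_fat": [0.981]})
        out = derive_traits(df)
        assert out["total_fat"].iloc[0] == pytest.approx(5.257, abs=1e-12)
        assert not out["total_fat_partial"].iloc[0]

    def test_total_fat_partial_when_perirenal_missing(self):
        df = pd.DataFrame({"inguinal_fat": [1.0], "gonadal_fat": [2.0]})
        out = derive_traits(df)
        assert out["total_fat"].iloc[0] == 3.0
        assert out["total_fat_partial"].iloc[0]

    def test_zero_components_give_zero_total(self):
        df = pd.DataFrame({"inguinal_fat": [0.0], "gonadal_fat": [0.0],
                           "perirenal_fat": [0.0]})
        assert derive_traits(df)["total_fat"].iloc[0] == 0.0

    def test_gains_are_successive_weight_differences(self):
        df = pd.DataFrame({"inguinal_fat": [1.0], "gonadal_fat": [1.0],
                           "perirenal_fat": [1.0],
                           "bw_wk13": [20.0], "bw_wk16": [23.0]})
        assert derive_traits(df)["gain_13_16"].iloc[0] == pytest.approx(3.0)

    def test_missing_component_raises(self):
        with pytest.raises(ValueError, match="fat pad"):
            derive_traits(pd.DataFrame({"inguinal_fat": [1.0]}))


class TestSelectFixedEffects:
    def test_alpha_one_retains_all_candidates(self, rng):
        df = toy_cohort(rng)
        spec = select_fixed_effects(df, "y", alpha=1.0)
        assert set(spec.fixed_terms) == {"parity", "litter_size",
                                         "parity:litter_size"}

    def test_strong_litter_size_effect_is_retained_null_parity_dropped(self):
        hits_ls, hits_par = 0, 0
        reps = 40
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            df = toy_cohort(rng, litter_size_beta=0.8, sigma_litter=0.3)
            spec = select_fixed_effects(df, "y")
            hits_ls += "litter_size" in spec.fixed_terms
            hits_par += "parity" in spec.fixed_terms
        assert hits_ls >= 0.9 * reps
        assert hits_par <= 0.3 * reps

    def test_all_null_candidates_yield_intercept_only_at_type_one_rate(self):
        reps, intercept_only = 50, 0
        for i in range(reps):
            rng = np.random.default_rng(2000 + i)
            df = toy_cohort(rng, sigma_litter=0.3)
            spec = select_fixed_effects(df, "y")
            intercept_only += not spec.fixed_terms
        # expected about (1 - alpha)^3 ~ 0.857 under independence of the
        # three candidate tests; allow generous Monte-Carlo slack
        assert 0.65 * reps <= intercept_only <= reps

    def test_interaction_kept_only_with_both_parents(self, rng):
        df = toy_cohort(rng, litter_size_beta=0.8)
        spec = select_fixed_effects(df, "y")
        if "parity:litter_size" in spec.fixed_terms:
            assert {"parity", "litter_size"} <= set(spec.fixed_terms)

    def test_single_litter_raises_degenerate_design(self, rng):
        df = toy_cohort(rng, n_litters=1)
        with pytest.raises(DegenerateDesignError):
            select_fixed_effects(df, "y")

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            select_fixed_effects(toy_cohort(rng), "y", candidates=[])


class TestAdjustTrait:
    def test_residual_mean_zero_and_orthogonal_to_design(self, rng):
        df = toy_cohort(rng, litter_size_beta=0.5, parity_beta=0.4,
                        bw_beta=2.0)
        spec = ModelSpec(fixed_terms=("parity", "litter_size"))
        fit = adjust_trait(df, "y", spec, covariate="bw_wk16")
        r = fit.residuals.dropna()
        assert abs(r.mean()) < 1e-8
        import patsy
        X = patsy.dmatrix("C(parity) + litter_size + bw_wk16", df,
                          return_type="dataframe")
        for col in X.columns:
            if X[col].std() == 0:
                continue
            assert abs(np.corrcoef(r, X.loc[r.index, col])[0, 1]) < 1e-6

    def test_covariate_adjustment_removes_bodyweight_correlation(self, rng):
        df = toy_cohort(rng, bw_beta=2.0, sigma_litter=0.0)
        fit = adjust_trait(df, "y", ModelSpec(fixed_terms=()),
                           covariate="bw_wk16")
        r = fit.residuals.dropna()
        assert abs(np.corrcoef(r, df.loc[r.index, "bw_wk16"])[0, 1]) < 1e-6

    def test_zero_litter_variance_matches_ols_residuals(self):
        # REML can estimate a small positive litter variance by chance even
        # when the truth is zero; this draw collapses to the boundary, which
        # must trigger the fixed-effects-only fallback
        rng = np.random.default_rng(0)
        df = toy_cohort(rng, sigma_litter=0.0, litter_size_beta=0.5)
        spec = ModelSpec(fixed_terms=("litter_size",))
        with pytest.warns(UserWarning, match="boundary"):
            fit = adjust_trait(df, "y", spec)
        ols = smf.ols("y ~ litter_size", data=df).fit()
        assert np.allclose(fit.residuals.dropna(),
                           ols.resid - ols.resid.mean(), atol=1e-6)
        assert not fit.mixed

    def test_reml_variance_component_recovery(self):
        reps = 30
        est_l, est_e = [], []
        for i in range(reps):
            rng = np.random.default_rng(3000 + i)
            df = toy_cohort(rng, n_litters=30, litter_size=8,
                            sigma_litter=1.0, sigma_e=1.0)
            fit = adjust_trait(df, "y", ModelSpec(fixed_terms=()))
            est_l.append(fit.var_litter)
            est_e.append(fit.var_residual)
        assert np.mean(est_l) == pytest.approx(1.0, rel=0.3)
        assert np.mean(est_e) == pytest.approx(1.0, rel=0.3)

    def test_missing_trait_values_propagate_not_dropped(self):
        rng = np.random.default_rng(5)
        df = toy_cohort(rng)
        df.loc[[3, 17], "y"] = np.nan
        fit = adjust_trait(df, "y", ModelSpec(fixed_terms=()))
        assert len(fit.residuals) == len(df)
        assert fit.residuals[[3, 17]].isna().all()
        assert fit.n == len(df) - 2

    def test_adjustment_on_simulated_cohort_runs_mixed(self):
        cohort = simulate_f2_intercross(
            CrossDesign.f2(n_animals=240, n_litters=30),
            MediationModel.causal(sigma_litter=0.4), seed=77)
        fit = adjust_trait(cohort, "inguinal_fat",
                           ModelSpec(fixed_terms=("parity",)))
        assert fit.mixed
        assert fit.var_litter > 0
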