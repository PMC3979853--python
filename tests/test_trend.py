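"""Bayesian hierarchical trend model: sampler, diagnostics, derived quantities."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

import nmixtrend as nt
from nmixtrend.design import ModelSpec
from nmixtrend.nmixture import NMixtureModel
from nmixtrend.trend import (
    TrendModel,
    TrendModelConfig,
    correction_factor_draws,
    extrapolate_population,
)

FAST = TrendModelConfig(n_iter=6000, n_burnin=1500, thin=5, seed=3)


def _quiet_fit(model, config, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return model.fit(config, **kw)


class TestSampler:
    def test_desk_fit_converges(self, desk_fit):
        assert desk_fit.converged
        assert max(desk_fit.rhat.values()) < 1.1
        assert not desk_fit.degenerate

    def test_latent_abundance_respects_support(self, study_dataset, desk_fit):
        ds, _ = study_dataset
        y, mask = ds.count_matrix()
        ymax = np.where(mask, y, 0).max(axis=1)
        assert np.all(desk_fit.n_draws >= ymax[None, None, :])

    def test_posterior_recovers_generating_effects(self, study_dataset, desk_fit):
        _, truth = study_dataset
        s = desk_fit.summary()
        inside = 0
        checks = [
            ("(Intercept)", truth.params.beta0),
            ("trend", truth.params.trend),
            ("water2", truth.params.beta_water[0]),
            ("water3", truth.params.beta_water[1]),
            ("water4", truth.params.beta_water[2]),
            ("det:year[1]", truth.alpha_year[0]),
            ("det:year[2]", truth.alpha_year[1]),
            ("det:year[3]", truth.alpha_year[2]),
            ("det:rain", truth.params.alpha_rain),
            ("det:veg2", truth.params.alpha_veg[0]),
            ("det:veg3", truth.params.alpha_veg[1]),
            ("det:veg4", truth.params.alpha_veg[2]),
            ("sigma_b", truth.params.sigma_b),
        ]
        for name, true_val in checks:
            inside += s.loc[name, "lcl"] <= true_val <= s.loc[name, "ucl"]
        assert inside >= 10  # ~95% nominal coverage over 13 parameters

    def test_seeded_runs_are_bit_reproducible(self, small_dataset):
        ds, _ = small_dataset
        r1 = _quiet_fit(TrendModel(ds), FAST)
        r2 = _quiet_fit(TrendModel(ds), FAST)
        np.testing.assert_array_equal(r1.theta_draws, r2.theta_draws)
        np.testing.assert_array_equal(r1.n_draws, r2.n_draws)

    def test_identical_chain_seeds_flag_degenerate(self, small_dataset):
        ds, _ = small_dataset
        cfg = dataclasses.replace(FAST, n_chains=2)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = TrendModel(ds).fit(cfg, chain_seeds=[7, 7])
        assert res.degenerate
        assert all(v == 1.0 for v in res.rhat.values())
        assert not res.converged

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrendModelConfig(n_iter=100, n_burnin=200)
        with pytest.raises(ValueError):
            TrendModelConfig(n_chains=1)

    def test_ml_and_bayes_agree_without_random_effect(self, small_dataset):
        # sigma_b forced to ~0 and no covariates: the posterior mean of
        # exp(beta0) must match the ML estimate of lambda within MC error
        ds, _ = small_dataset
        spec = ModelSpec(None, ())
        ml = NMixtureModel(ds, spec).fit(n_starts=3, seed=0)
        cfg = dataclasses.replace(FAST, sigma_b_upper=1e-3)
        bayes = _quiet_fit(TrendModel(ds, abundance_covariate=None, detection_terms=()), cfg)
        lam_ml = float(np.exp(ml.beta[0]))
        lam_bayes = float(np.exp(bayes.posterior["(Intercept)"]).mean())
        assert lam_bayes == pytest.approx(lam_ml, rel=0.05)


class TestDerivedQuantities:
    def test_annual_totals_concentrate_under_perfect_detection(self):
        pars = dataclasses.replace(
            nt.StudyParameters(),
            sigma_b=0.0,
            beta_water=(0.0, 0.0, 0.0),
            alpha_det=20.0,
            sigma_year=0.0,
            alpha_rain=0.0,
            alpha_veg=(0.0, 0.0, 0.0),
        )
        ds, truth = nt.generate_dataset(nt.GeneratorConfig(seed=21, n_transects=6, n_years=2, params=pars))
        res = _quiet_fit(TrendModel(ds, abundance_covariate=None, detection_terms=()), FAST)
        totals = res.annual_totals()
        observed = truth.N.reshape(6, 2).sum(axis=0)
        for year, obs in zip(totals.index, observed):
            assert totals.loc[year, "mean"] == pytest.approx(obs, abs=0.5)

    def test_totals_never_below_max_round_total(self, study_dataset, desk_fit):
        ds, _ = study_dataset
        max_round = ds.round_totals().max(axis=1)
        totals = desk_fit.annual_total_draws()
        for year in totals.columns:
            assert (totals[year] >= max_round[year]).all()

    def test_correction_factor_point_arithmetic(self):
        # published 2012 numbers: mean total 780 against round totals
        # 542/574/608 gives 780/608 = 1.28
        totals = pd.DataFrame({2012: [780.0]})
        max_round = pd.Series({2012: max(542, 574, 608)})
        factor = correction_factor_draws(totals, max_round)[2012].iloc[0]
        assert round(factor, 2) == 1.28

    def test_correction_factor_identity(self):
        totals = pd.DataFrame({1: [600.0]})
        factor = correction_factor_draws(totals, pd.Series({1: 600.0}))[1].iloc[0]
        assert factor == 1.0

    def test_zero_round_total_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            correction_factor_draws(pd.DataFrame({1: [5.0]}), pd.Series({1: 0.0}))

    def test_extrapolation_identity_and_linearity(self):
        assert extrapolate_population(2594, np.ones(100))["mean"] == 2594
        rng = np.random.default_rng(0)
        draws = rng.normal(1.3, 0.05, 4000)
        one = extrapolate_population(1000, draws)
        two = extrapolate_population(2000, draws)
        assert two["mean"] == pytest.approx(2 * one["mean"], abs=1)

    def test_trend_percent_transform(self, desk_fit):
        ts = desk_fit.trend_summary()
        assert ts["pct_change_lcl"] == pytest.approx(100 * (np.exp(ts["lcl"]) - 1), abs=1e-9)
        assert ts["pct_change_ucl"] == pytest.approx(100 * (np.exp(ts["ucl"]) - 1), abs=1e-9)
        r = 0.08
        assert round(100 * (np.exp(r) - 1)) == 8  # printed-style rounding

    def test_zero_trend_draws_give_zero_percent(self, small_dataset):
        ds, _ = small_dataset
        res = _quiet_fit(TrendModel(ds), FAST)
        res.theta_draws[:, :, res.param_names.index("trend")] = 0.0
        assert res.trend_summary()["pct_change_per_year"] == 0.0


class TestPosteriorPredictiveCheck:
    def test_deterministic_given_seed(self, desk_fit):
        a = desk_fit.posterior_predictive_check(seed=5)
        b = desk_fit.posterior_predictive_check(seed=5)
        assert a.p_value == b.p_value and a.slope == b.slope

    def test_self_generated_data_fits(self, desk_fit):
        ppc = desk_fit.posterior_predictive_check(seed=1)
        assert 0.05 < ppc.p_value < 0.95
        assert ppc.slope == pytest.approx(1.0, abs=0.15)

    def test_overdispersed_data_rejected(self, study_dataset):
        # corrupt the counts with visit-level gamma noise (variance ~10x the
        # binomial-Poisson level); the check must flag misfit
        ds, truth = study_dataset
        rng = np.random.default_rng(99)
        m = truth.lam[:, None] * truth.p  # per-visit means
        g = rng.gamma(1.0 / 9.0, 9.0, size=m.shape)
        bad_counts = ds.counts.copy()
        bad_counts["count"] = rng.poisson(m * g).reshape(-1).astype("int64")
        bad = nt.SurveyDataset(bad_counts, ds.site_cov, ds.obs_cov)
        res = _quiet_fit(TrendModel(bad), FAST)
        ppc = res.posterior_predictive_check(seed=2)
        assert ppc.p_value < 0.05
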