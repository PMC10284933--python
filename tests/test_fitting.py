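import math

import numpy as np
import pytest

import stabkin as sk
from stabkin.data import AttributeTransform, ExtentObservations
from stabkin.errors import IdentifiabilityError
from stabkin.fitting import (
    FitOptions,
    fit_concentration_dependent,
    fit_model,
    information_criteria,
    merge_observations,
    robustness_check,
)
from stabkin.integrator import extent_at_observations
from stabkin.kinetics import (
    KineticParameters,
    first_order_spec,
    nth_order_spec,
    zero_order_spec,
)
from stabkin.synthetic import generate_dataset, preset
from stabkin.units import celsius_to_kelvin


class TestInformationCriteria:
    def test_least_squares_aic_formula(self):
        # N=30, RSS=0.3, K=3 -> AIC = 30 ln(0.01) + 2*4
        aic, aicc, bic = information_criteria(0.3, 30, 3)
        assert aic == pytest.approx(30 * math.log(0.01) + 8, abs=1e-9)
        assert aicc == pytest.approx(aic + 2 * 4 * 5 / (30 - 5), abs=1e-9)
        assert bic == pytest.approx(30 * math.log(0.01) + 4 * math.log(30), abs=1e-9)

    def test_aicc_exceeds_aic_for_finite_samples(self):
        aic, aicc, _ = information_criteria(1.0, 25, 4)
        assert aicc > aic

    def test_too_few_observations_refused(self):
        with pytest.raises(IdentifiabilityError):
            information_criteria(0.1, 5, 3)


def _noiseless_obs(cfg):
    ds, truth = generate_dataset(cfg.with_(sigma=0.0), seed=0)
    return sk.to_extent(ds, cfg.transform)


class TestFitModel:
    def test_noiseless_first_order_recovers_rates(self):
        cfg = preset("live-attenuated-titer")
        obs = _noiseless_obs(cfg)
        fit = fit_model(first_order_spec(), obs)
        assert fit.converged
        assert fit.rss < 1e-10
        for arm_C in (5.0, 25.0, 40.0):
            T = celsius_to_kelvin(arm_C)
            k_true = math.exp(cfg.params.lnA1 - cfg.params.Ea1 / (sk.GAS_CONSTANT * T))
            assert fit.k_at(T) == pytest.approx(k_true, rel=1e-3)

    def test_noiseless_recovery_across_one_step_presets(self):
        for name in ("mab-acidic-variants", "hmw-aggregation"):
            cfg = preset(name)
            obs = _noiseless_obs(cfg)
            fit = fit_model(cfg.spec, obs)
            assert fit.params.Ea1 == pytest.approx(cfg.params.Ea1, rel=1e-3)
            assert fit.params.lnA1 == pytest.approx(cfg.params.lnA1, rel=1e-3)

    def test_degenerate_flat_data_zero_rate(self):
        t = np.tile([0.0, 30.0, 90.0, 180.0], 3)
        T = np.repeat(celsius_to_kelvin(np.array([5.0, 25.0, 40.0])), 4)
        obs = ExtentObservations(t, T, np.zeros_like(t))
        fit = fit_model(zero_order_spec(), obs)
        assert fit.rss < 1e-9
        assert fit.k_at(313.15) < 1e-6  # essentially no degradation

    def test_refuses_underdetermined_fit(self):
        obs = ExtentObservations(
            np.array([0.0, 10.0, 20.0, 30.0]),
            np.full(4, 298.15),
            np.array([0.0, 0.1, 0.2, 0.3]),
        )
        with pytest.raises(IdentifiabilityError):
            fit_model(nth_order_spec(), obs)  # N=4, K=3 -> N <= K+2

    def test_record_order_invariance(self, mab_obs):
        fit = fit_model(nth_order_spec(), mab_obs)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(mab_obs))
        shuffled = ExtentObservations(
            mab_obs.time_days[perm], mab_obs.temp_K[perm], mab_obs.alpha[perm]
        )
        fit2 = fit_model(nth_order_spec(), shuffled)
        assert np.allclose(fit.params.as_array(), fit2.params.as_array(), rtol=1e-6)

    def test_seeded_fit_is_bit_reproducible(self, mab_obs):
        a = fit_model(nth_order_spec(), mab_obs, FitOptions(seed=7))
        b = fit_model(nth_order_spec(), mab_obs, FitOptions(seed=7))
        assert a.params.as_array().tobytes() == b.params.as_array().tobytes()
        assert a.rss == b.rss


class TestConcentrationDependence:
    def test_recovers_unit_exponent(self):
        cfg = preset("concentration-dimer")
        ds, _ = generate_dataset(cfg, seed=12)
        obs = sk.to_extent(ds, cfg.transform)
        fit = fit_concentration_dependent(cfg.spec, obs)
        assert fit.params.p1 == pytest.approx(1.0, abs=0.15)

    def test_fixed_zero_exponent_matches_blind_fit(self):
        cfg = preset("concentration-dimer")
        ds, _ = generate_dataset(cfg.with_(concentrations=(80.0,)), seed=1)
        obs = sk.to_extent(ds, cfg.transform)
        blind = fit_model(first_order_spec(), ExtentObservations(
            obs.time_days, obs.temp_K, obs.alpha))
        fixed = fit_concentration_dependent(first_order_spec(), obs)
        assert np.allclose(blind.params.as_array(), fixed.params.as_array(), rtol=1e-8)

    def test_identical_curves_force_zero_exponent(self):
        # same kinetics at both concentrations -> p must come out ~0;
        # lnA is boosted to keep the degradation magnitude comparable to
        # the preset once the C^p factor is removed
        cfg = preset("concentration-dimer")
        truth = cfg.params.replace(p1=0.0, lnA1=cfg.params.lnA1 + math.log(100.0))
        ds, _ = generate_dataset(cfg.with_(params=truth), seed=4)
        obs = sk.to_extent(ds, cfg.transform)
        fit = fit_concentration_dependent(cfg.spec, obs)
        assert abs(fit.params.p1) < 0.15

    def test_single_concentration_with_free_p_refused(self):
        cfg = preset("concentration-dimer")
        ds, _ = generate_dataset(cfg.with_(concentrations=(80.0,)), seed=1)
        obs = sk.to_extent(ds, cfg.transform)
        with pytest.raises(IdentifiabilityError):
            fit_concentration_dependent(cfg.spec, obs)

    def test_merge_observations_concatenates(self):
        cfg = preset("concentration-dimer")
        ds, _ = generate_dataset(cfg, seed=1)
        obs = sk.to_extent(ds, cfg.transform)
        half = len(obs) // 2
        merged = merge_observations(
            [obs.subset(np.arange(half)), obs.subset(np.arange(half, len(obs)))]
        )
        assert len(merged) == len(obs)


class TestRobustness:
    def test_single_generative_law_is_robust_across_ranges(self):
        cfg = preset("mab-acidic-variants")
        obs = _noiseless_obs(cfg)
        report = robustness_check(cfg.spec, obs, [(5.0, 40.0), (5.0, 25.0)])
        assert report.robust
        deltas = [e.delta_ea_rel for e in report.entries]
        assert max(deltas) < 1e-3

    def test_pathway_change_detected_as_not_robust(self):
        # arms up to 40 degC follow Ea = 100 kJ/mol; a 55 degC arm degrades
        # 10x faster than that law extrapolates (different pathway)
        cfg = preset("mab-acidic-variants")
        base = cfg.with_(sigma=0.0)
        ds, _ = generate_dataset(base, seed=0)
        obs = sk.to_extent(ds, cfg.transform)
        t = np.array([0.0, 7.6, 15.2, 30.4, 60.9, 91.3, 182.6])
        T_hot = celsius_to_kelvin(55.0)
        hot_params = cfg.params.replace(lnA1=cfg.params.lnA1 + math.log(10.0))
        alpha_hot = extent_at_observations(hot_params, t, np.full_like(t, T_hot))
        obs_all = ExtentObservations(
            np.concatenate([obs.time_days, t]),
            np.concatenate([obs.temp_K, np.full_like(t, T_hot)]),
            np.concatenate([obs.alpha, alpha_hot]),
        )
        report = robustness_check(cfg.spec, obs_all, [(5.0, 40.0)])
        assert not report.robust
        assert report.entries[0].delta_ea_rel > 0.20

    def test_range_with_too_few_arms_skipped(self, mab_obs):
        cfg = preset("mab-acidic-variants")
        report = robustness_check(cfg.spec, mab_obs, [(38.0, 42.0), (5.0, 40.0)])
        assert report.entries[0].skipped_reason is not None
        assert report.entries[1].fit is not None

    def test_full_range_only_gives_zero_delta(self, mab_obs):
        cfg = preset("mab-acidic-variants")
        report = robustness_check(cfg.spec, mab_obs, [(5.0, 40.0)])
        assert report.entries[0].delta_ea_rel == pytest.approx(0.0, abs=1e-6)


class TestNestedModels:
    def test_general_model_rss_not_worse_than_special_case(self, mab_obs):
        ranking = sk.screen_models(sk.default_catalog(), mab_obs)
        rss = {r.spec.name: r.rss for r in ranking.results}
        tol = 1e-9
        assert rss["nth-order"] <= rss["first-order"] + tol
        assert rss["nth-order"] <= rss["zero-order"] + tol
        assert rss["autocatalytic"] <= rss["nth-order"] + tol
        assert rss["two-step"] <= rss["autocatalytic"] + tol
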