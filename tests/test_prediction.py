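import math

import numpy as np
import pytest

import stabkin as sk
from stabkin.data import AttributeTransform
from stabkin.errors import IdentifiabilityError
from stabkin.kinetics import GAS_CONSTANT, KineticParameters, ModelCatalog, first_order_spec
from stabkin.prediction import (
    compare_batches,
    excursion_monitor,
    ich_q1e_baseline,
    shelf_life,
)
from stabkin.profiles import TemperatureProfile
from stabkin.selection import PredictionBand, ensemble_band, residual_bootstrap, screen_models
from stabkin.synthetic import generate_dataset, preset
from stabkin.units import DAYS_PER_MONTH


def _linear_band(rate_per_month, y0=1.0, horizon_m=24.0, half_width=0.0, level=0.95):
    t = np.linspace(0, horizon_m * DAYS_PER_MONTH, 500)
    central = y0 + rate_per_month * t / DAYS_PER_MONTH
    return PredictionBand(t, central, central - half_width, central + half_width, level)


class TestShelfLife:
    def test_linear_growth_crosses_at_five_months(self):
        band = _linear_band(1.0)
        est = shelf_life(band, spec_limit=6.0, direction=1)  # +5 over baseline 1.0
        assert est.t_central_months == pytest.approx(5.0, abs=1e-6)
        assert est.t_band_months == pytest.approx(5.0, abs=1e-6)

    def test_wider_band_shortens_banded_shelf_life(self):
        tight = shelf_life(_linear_band(1.0, half_width=0.2), 6.0, 1)
        wide = shelf_life(_linear_band(1.0, half_width=1.0), 6.0, 1)
        assert wide.t_band < tight.t_band < tight.t_central

    def test_limit_above_asymptote_is_beyond_horizon(self):
        t = np.linspace(0, 1000, 300)
        central = 1.0 + 4.0 * (1 - np.exp(-t / 100.0))  # saturates at 5.0
        band = PredictionBand(t, central, central, central, 0.95)
        est = shelf_life(band, spec_limit=6.0, direction=1)
        assert est.t_central is None and est.t_band is None

    def test_limit_already_violated_flags_zero_shelf_life(self):
        band = _linear_band(1.0, y0=10.0)
        est = shelf_life(band, spec_limit=6.0, direction=1)
        assert est.zero_shelf_life and est.t_band == 0.0

    def test_raising_limit_never_shortens_shelf_life(self):
        band = _linear_band(0.7, half_width=0.1)
        ts = [
            shelf_life(band, lim, 1).t_central
            for lim in (3.0, 5.0, 8.0, 12.0)
        ]
        assert ts == sorted(ts)


class TestIchBaseline:
    def test_exact_crossing_on_noiseless_line(self):
        # y = 100 - 0.5 t(months); limit 94 -> t = 12 months
        t = np.arange(0, 13, 2.0) * DAYS_PER_MONTH
        y = 100.0 - 0.5 * t / DAYS_PER_MONTH
        est = ich_q1e_baseline(t, y, spec_limit=94.0, direction=-1)
        assert est.t_cross_months == pytest.approx(12.0, abs=1e-3)
        assert est.t_central == pytest.approx(est.t_cross, abs=1e-3)

    def test_confidence_limit_shortens_noisy_shelf_life(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 13, 1.0) * DAYS_PER_MONTH
        y = 100.0 - 0.5 * t / DAYS_PER_MONTH + rng.normal(0, 0.3, len(t))
        est = ich_q1e_baseline(t, y, spec_limit=94.0, direction=-1)
        assert est.t_cross < est.t_central

    def test_wrong_sign_slope_is_beyond_horizon(self):
        t = np.array([0.0, 90.0, 180.0, 365.0])
        y = np.array([100.0, 100.4, 100.9, 101.8])  # improving, never degrading
        est = ich_q1e_baseline(t, y, spec_limit=94.0, direction=-1)
        assert est.degenerate and est.t_cross is None

    def test_needs_three_points(self):
        with pytest.raises(IdentifiabilityError):
            ich_q1e_baseline([0.0, 30.0], [1.0, 2.0], 5.0, 1)


class TestExcursionMonitor:
    def test_ten_x_excursion_adds_nine_equivalent_days(self, first_order_ranking):
        # zero-order model whose rate at 25 degC is exactly 10x the 5 degC rate
        Ea = GAS_CONSTANT * math.log(10.0) / (1 / 278.15 - 1 / 298.15)
        params = KineticParameters(
            lnA1=math.log(1e-4) + Ea / (GAS_CONSTANT * 278.15), Ea1=Ea, n1=0.0, m1=0.0
        )
        cfg, ranking = first_order_ranking
        fit = ranking.best
        fit_zero = type(fit)(**{**fit.__dict__, "params": params})
        profile = TemperatureProfile(
            np.array([0.0, 30.0, 31.0, 60.0]),
            np.array([278.15, 298.15, 278.15, 278.15]),
            interpolation="hold",
        )
        grid = np.linspace(0, 60, 61)
        rep = excursion_monitor(fit_zero, profile, cfg.transform, grid)
        assert rep.equivalent_days_at_ref - 60.0 == pytest.approx(9.0, abs=1e-9)

    def test_constant_profile_reproduces_standard_band_exactly(self, first_order_ranking):
        cfg, ranking = first_order_ranking
        prof = TemperatureProfile.isothermal_celsius(5.0)
        grid = np.linspace(0, 500, 51)
        ens, band = residual_bootstrap(
            ranking, B=150, seed=4, target_profile=prof, grid=grid,
            transform=cfg.transform,
        )
        rep = excursion_monitor(
            ranking.best, prof, cfg.transform, grid, ensemble=ens, level=band.level
        )
        assert np.array_equal(rep.band.central, band.central)
        assert np.array_equal(rep.band.lower, band.lower)
        assert np.array_equal(rep.band.upper, band.upper)

    def test_logger_gap_produces_warning_annotation(self, first_order_ranking):
        cfg, ranking = first_order_ranking
        prof = TemperatureProfile(
            np.array([0.0, 1.0, 8.0]), np.array([278.15, 279.15, 278.15])
        )
        rep = excursion_monitor(
            ranking.best, prof, cfg.transform, np.linspace(0, 8, 9),
            gap_threshold_days=2.0,
        )
        assert any("gap" in w for w in rep.warnings)


class TestBatchComparison:
    def test_self_comparison_is_comparable_with_zero_deltas(self, titer_dataset, first_order_ranking):
        cfg, ds, _ = titer_dataset
        _, ranking = first_order_ranking
        ens, _ = residual_bootstrap(ranking, B=200, seed=8)
        result = compare_batches(ranking.best, ens, ds, cfg.transform)
        assert result.comparable
        assert result.rate_ratio_at_ref == pytest.approx(1.0, abs=1e-6)
        assert result.delta_Ea1 == pytest.approx(0.0, abs=1.0)

    def test_doubled_rate_batch_not_comparable(self, titer_dataset, first_order_ranking):
        cfg, _, _ = titer_dataset
        _, ranking = first_order_ranking
        fast = cfg.with_(params=cfg.params.replace(lnA1=cfg.params.lnA1 + math.log(2.0)))
        ds_b, _ = generate_dataset(fast, seed=21)
        ens, _ = residual_bootstrap(ranking, B=200, seed=8)
        result = compare_batches(ranking.best, ens, ds_b, cfg.transform)
        assert not result.comparable
        assert result.inclusion_fraction < 0.95
        assert result.rate_ratio_at_ref == pytest.approx(2.0, rel=0.15)

    def test_disjoint_arms_refused(self, titer_dataset, first_order_ranking):
        cfg, ds, _ = titer_dataset
        _, ranking = first_order_ranking
        shifted = ds.frame.copy()
        shifted["temperature_C"] = shifted["temperature_C"] + 50.0
        ds_b = type(ds)(shifted)
        ens, _ = residual_bootstrap(ranking, B=100, seed=0)
        with pytest.raises(IdentifiabilityError):
            compare_batches(ranking.best, ens, ds_b, cfg.transform)
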