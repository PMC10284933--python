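import math

import numpy as np
import pytest

import stabkin as sk
from stabkin.data import AttributeTransform
from stabkin.errors import DomainError
from stabkin.integrator import (
    extent_at_observations,
    integrate_extent,
    predict_attribute,
    step_extent,
    theta_integral,
)
from stabkin.kinetics import KineticParameters
from stabkin.profiles import TemperatureProfile

FIRST_ORDER_005 = KineticParameters(lnA1=math.log(0.05), Ea1=0.0, n1=1.0)

#: representative parameters for each default-catalog shape
CATALOG_PARAMS = {
    "zero-order": KineticParameters(lnA1=24.5, Ea1=80_000.0, n1=0.0, m1=0.0),
    "first-order": KineticParameters(lnA1=20.0, Ea1=65_000.0, n1=1.0, m1=0.0),
    "nth-order": KineticParameters(lnA1=32.9, Ea1=100_000.0, n1=1.5, m1=0.0),
    "autocatalytic": KineticParameters(lnA1=25.0, Ea1=75_000.0, n1=1.0, m1=0.7),
    "two-step": KineticParameters(
        lnA1=14.3, Ea1=40_000.0, n1=1.0, m1=0.0,
        lnA2=37.7, Ea2=110_000.0, n2=1.0, m2=0.0, v=0.3,
    ),
}


class TestClosedFormOracles:
    def test_first_order_isothermal_matches_exponential(self):
        prof = TemperatureProfile.isothermal(278.15)
        curve = integrate_extent(FIRST_ORDER_005, prof, [0.0, 10.0], alpha0=0.0)
        assert curve.alpha[-1] == pytest.approx(1 - math.exp(-0.5), abs=1e-8)
        assert curve.alpha[-1] == pytest.approx(0.393469, abs=1e-6)

    def test_zero_order_piecewise_accumulation(self):
        # 10 d at k=0.001/d then 1 d at k=0.01/d (step-hold) -> alpha = 0.020
        Ea = 150_000.0
        lnA_a = math.log(0.001) + Ea / (sk.GAS_CONSTANT * 278.15)
        k_b = 0.01
        # temperature at which this lnA/Ea give k_b
        T_b = Ea / (sk.GAS_CONSTANT * (lnA_a - math.log(k_b)))
        p = KineticParameters(lnA1=lnA_a, Ea1=Ea, n1=0.0, m1=0.0)
        prof = TemperatureProfile(
            np.array([0.0, 10.0, 11.0]), np.array([278.15, T_b, T_b]),
            interpolation="hold",
        )
        curve = integrate_extent(p, prof, [0.0, 11.0], alpha0=0.0)
        assert curve.alpha[-1] == pytest.approx(0.020, abs=1e-7)

    def test_single_point_grid_returns_initial_extent(self):
        prof = TemperatureProfile.isothermal(298.15)
        curve = integrate_extent(FIRST_ORDER_005, prof, [0.0], alpha0=0.007)
        assert curve.alpha[0] == 0.007


class TestRouteEquivalence:
    @pytest.mark.parametrize("name", sorted(CATALOG_PARAMS))
    def test_fast_route_matches_ivp_route(self, name):
        p = CATALOG_PARAMS[name]
        prof = TemperatureProfile.from_knots_celsius([(0, 5), (30, 40), (60, 5), (90, 5)])
        grid = np.linspace(0, 120, 25)
        ref = integrate_extent(p, prof, grid)
        fast = integrate_extent(p, prof, grid, method="fast")
        assert np.max(np.abs(ref.alpha - fast.alpha)) < 1e-6

    @pytest.mark.parametrize("name", sorted(CATALOG_PARAMS))
    def test_constant_profile_equals_isothermal(self, name):
        p = CATALOG_PARAMS[name]
        grid = np.linspace(0, 180, 13)
        iso = integrate_extent(p, TemperatureProfile.isothermal(298.15), grid)
        const = integrate_extent(
            p,
            TemperatureProfile(np.array([0.0, 90.0, 180.0]), np.full(3, 298.15)),
            grid,
        )
        assert np.max(np.abs(iso.alpha - const.alpha)) < 1e-7

    @pytest.mark.parametrize("name", sorted(CATALOG_PARAMS))
    def test_segment_splitting_semigroup(self, name):
        p = CATALOG_PARAMS[name]
        prof = TemperatureProfile.from_knots_celsius([(0, 5), (40, 35), (80, 5), (150, 5)])
        full = integrate_extent(p, prof, [0.0, 60.0, 150.0])
        first = integrate_extent(p, prof, [0.0, 60.0])
        second = integrate_extent(
            p, prof, [60.0, 150.0], alpha0=(first.alpha1[-1], first.alpha2[-1])
        )
        assert second.alpha[-1] == pytest.approx(full.alpha[-1], abs=1e-6)


class TestPhysicalInvariants:
    @pytest.mark.parametrize("name", sorted(CATALOG_PARAMS))
    def test_extent_nondecreasing_and_bounded(self, name):
        p = CATALOG_PARAMS[name]
        grid = np.linspace(0, 365, 80)
        curve = integrate_extent(p, TemperatureProfile.isothermal(313.15), grid)
        assert np.all(np.diff(curve.alpha) >= -1e-12)
        assert np.all((curve.alpha >= 0) & (curve.alpha <= 1))

    def test_warmer_profile_degrades_more(self):
        p = CATALOG_PARAMS["first-order"]
        grid = [0.0, 365.0]
        cold = integrate_extent(p, TemperatureProfile.isothermal_celsius(5.0), grid)
        warm = integrate_extent(p, TemperatureProfile.isothermal_celsius(15.0), grid)
        assert warm.alpha[-1] > cold.alpha[-1]

    def test_equivalent_time_superposition_first_order(self):
        # under any profile, alpha = 1 - exp(-theta(t)) for first-order
        p = CATALOG_PARAMS["first-order"]
        prof = TemperatureProfile.from_knots_celsius([(0, 5), (50, 30), (100, 5), (200, 5)])
        grid = np.array([0.0, 75.0, 200.0])
        curve = integrate_extent(p, prof, grid, alpha0=0.0)
        theta = theta_integral(prof, p.lnA1, p.Ea1, grid)
        assert np.allclose(curve.alpha, 1 - np.exp(-theta), atol=1e-7)


class TestThetaIntegral:
    def test_isothermal_theta_is_k_times_t(self):
        prof = TemperatureProfile.isothermal(298.15)
        k = sk.arrhenius_k(20.0, 65_000.0, 298.15)
        theta = theta_integral(prof, 20.0, 65_000.0, [0.0, 100.0])
        assert theta[1] == pytest.approx(100 * k, rel=1e-12)

    def test_linear_ramp_quadrature(self):
        # oracle: dense trapezoid integration of k(T(s))
        prof = TemperatureProfile(np.array([0.0, 50.0]), np.array([278.15, 313.15]))
        s = np.linspace(0, 50, 200_001)
        k = sk.arrhenius_k(20.0, 80_000.0, prof.temperature_at(s))
        expected = np.trapezoid(k, s)
        got = theta_integral(prof, 20.0, 80_000.0, [50.0])[0]
        assert got == pytest.approx(expected, rel=1e-9)


class TestStepExtent:
    @pytest.mark.parametrize("n", [0.0, 0.5, 1.0, 1.7, 2.5])
    def test_closed_forms_solve_the_ode(self, n):
        # differentiate the closed form numerically and compare to the rate law
        theta = np.linspace(0.01, 0.7, 50)
        a = step_extent(theta, n, 0.0, alpha0=0.0)
        da = np.gradient(a, theta)
        inside = (a < 0.9)
        inside[0] = inside[-1] = False  # one-sided differences are too crude
        assert np.allclose(da[inside], (1 - a[inside]) ** n, rtol=5e-3, atol=5e-4)

    def test_autocatalytic_needs_seed_extent(self):
        assert step_extent(np.array([5.0]), 1.0, 1.0, alpha0=0.0)[0] == 0.0
        assert step_extent(np.array([50.0]), 1.0, 1.0, alpha0=1e-8)[0] > 0.99

    def test_negative_reduced_time_rejected(self):
        with pytest.raises(DomainError):
            step_extent(np.array([-0.5]), 1.0, 0.0)


class TestAttributePrediction:
    def test_increasing_attribute(self):
        tr = AttributeTransform(y0=0.5, span=10.0, direction=1)
        assert predict_attribute(np.array([0.2]), tr)[0] == pytest.approx(2.5)

    def test_decreasing_attribute(self):
        tr = AttributeTransform(y0=100.0, span=100.0, direction=-1)
        assert predict_attribute(np.array([0.2]), tr)[0] == pytest.approx(80.0)

    def test_zero_extent_returns_baseline(self):
        tr = AttributeTransform(y0=7.0, span=3.0, direction=1)
        assert predict_attribute(np.array([0.0]), tr)[0] == 7.0


class TestObservationEvaluator:
    def test_matches_isothermal_integration_per_arm(self):
        p = CATALOG_PARAMS["two-step"]
        t = np.array([0.0, 30.0, 90.0, 30.0, 90.0])
        T = np.array([278.15, 278.15, 278.15, 313.15, 313.15])
        pred = extent_at_observations(p, t, T)
        for Ti in (278.15, 313.15):
            sel = T == Ti
            grid = np.union1d([0.0], t[sel])  # arms are held at T since t = 0
            curve = integrate_extent(p, TemperatureProfile.isothermal(Ti), grid)
            at_obs = np.interp(np.sort(t[sel]), grid, curve.alpha)
            assert np.allclose(np.sort(pred[sel]), at_obs, atol=1e-6)
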