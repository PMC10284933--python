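"""Downstream uses of a fitted kinetic model: shelf-life, the classical
ICH Q1E regression baseline, cold-chain excursion monitoring, and
batch-to-batch comparability.

Shelf-life is the first time the predicted attribute (central curve) or the
conservative band edge crosses the specification limit under the storage
profile.  The ICH Q1E baseline is the classical single-arm alternative:
an ordinary least-squares line through the storage-temperature data, with
shelf-life read where the one-sided 95 % confidence limit on the regression
mean meets the limit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import StabilityDataset, to_extent
from .errors import DomainError, IdentifiabilityError
from .fitting import FitOptions, FitResult, fit_model
from .integrator import integrate_extent, theta_integral
from .kinetics import GAS_CONSTANT
from .selection import BootstrapEnsemble, PredictionBand, ensemble_band
from .profiles import TemperatureProfile
from .units import days_to_months, celsius_to_kelvin

__all__ = [
    "ShelfLifeEstimate",
    "shelf_life",
    "IchEstimate",
    "ich_q1e_baseline",
    "ExcursionReport",
    "excursion_monitor",
    "BatchComparison",
    "compare_batches",
]


def _first_crossing(times, values, limit: float, direction: int) -> float | None:
    """Earliest time the piecewise-linear curve reaches the limit.

    ``direction`` +1: degradation raises the attribute, crossing means
    value >= limit; -1: crossing means value <= limit.  Returns None when
    no crossing occurs on the grid ("beyond horizon").
    """
    v = np.asarray(values, dtype=float) * direction
    t = np.asarray(times, dtype=float)
    lim = limit * direction
    if v[0] >= lim:
        return float(t[0])
    hit = np.nonzero(v >= lim)[0]
    if len(hit) == 0:
        return None
    i = hit[0]
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (lim - v0) / (v1 - v0) * (t1 - t0))


@dataclass
class ShelfLifeEstimate:
    spec_limit: float
    direction: int
    t_central: float | None  # days; None = beyond horizon
    t_band: float | None
    level: float
    horizon: float
    zero_shelf_life: bool = False

    @property
    def t_central_months(self) -> float | None:
        return None if self.t_central is None else days_to_months(self.t_central)

    @property
    def t_band_months(self) -> float | None:
        return None if self.t_band is None else days_to_months(self.t_band)

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec_limit": self.spec_limit,
                "direction": self.direction,
                "t_central_days": self.t_central,
                "t_band_days": self.t_band,
                "t_central_months": self.t_central_months,
                "t_band_months": self.t_band_months,
                "level": self.level,
                "horizon_days": self.horizon,
                "zero_shelf_life": self.zero_shelf_life,
            },
            indent=2,
        )


def shelf_life(band: PredictionBand, spec_limit: float, direction: int) -> ShelfLifeEstimate:
    """Crossing times of the central curve and the conservative band edge.

    The conservative edge is the one nearer the limit: upper for an
    attribute that grows with degradation, lower for one that falls.
    """
    if len(band.times) < 2:
        raise DomainError("band grid too coarse for crossing search")
    conservative = band.upper if direction == 1 else band.lower
    t_central = _first_crossing(band.times, band.central, spec_limit, direction)
    t_band = _first_crossing(band.times, conservative, spec_limit, direction)
    zero = bool(t_band is not None and t_band <= band.times[0])
    return ShelfLifeEstimate(
        spec_limit=spec_limit,
        direction=direction,
        t_central=t_central,
        t_band=t_band,
        level=band.level,
        horizon=float(band.times[-1]),
        zero_shelf_life=zero,
    )


@dataclass
class IchEstimate:
    slope_per_day: float
    intercept: float
    t_cross: float | None  # one-sided CL crossing, days
    t_central: float | None  # fitted-line crossing, days
    level: float
    n: int
    degenerate: bool = False

    @property
    def t_cross_months(self) -> float | None:
        return None if self.t_cross is None else days_to_months(self.t_cross)

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope_per_day": self.slope_per_day,
                "intercept": self.intercept,
                "t_cross_days": self.t_cross,
                "t_central_days": self.t_central,
                "level": self.level,
                "n": self.n,
                "degenerate": self.degenerate,
            },
            indent=2,
        )


def ich_q1e_baseline(
    time_days,
    values,
    spec_limit: float,
    direction: int,
    level: float = 0.95,
    horizon_days: float = 3653.0,
) -> IchEstimate:
    """Classical single-batch ICH Q1E shelf-life by linear regression.

    OLS of attribute vs time through the storage-arm data only; shelf-life
    is the earliest time where the one-sided ``level`` confidence limit on
    the regression mean crosses ``spec_limit``.
    """
    t = np.asarray(time_days, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise IdentifiabilityError("ICH baseline needs at least 3 time points at one temperature")
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])

    # degradation must move the attribute toward the limit
    if slope * direction <= 0:
        return IchEstimate(slope, intercept, None, None, level, len(t), degenerate=True)

    n = len(t)
    dof = n - 2
    s2 = float(res.ssr) / dof if dof > 0 else 0.0
    tbar = t.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    tq = stats.t.ppf(level, dof) if dof > 0 else 0.0

    def bound(tt):
        mean = intercept + slope * tt
        se = math.sqrt(s2 * (1.0 / n + (tt - tbar) ** 2 / sxx)) if sxx > 0 else 0.0
        return mean + direction * tq * se  # one-sided limit toward the spec limit

    grid = np.linspace(0.0, horizon_days, 4000)
    t_cross = _first_crossing(grid, [bound(tt) for tt in grid], spec_limit, direction)
    if t_cross is not None and 0 < t_cross < horizon_days:
        # polish with a root bracket around the grid estimate
        from scipy.optimize import brentq

        f = lambda tt: direction * (bound(tt) - spec_limit)
        a = max(0.0, t_cross - horizon_days / 3999)
        b = min(horizon_days, t_cross + horizon_days / 3999)
        if f(a) * f(b) < 0:
            t_cross = float(brentq(f, a, b, xtol=1e-6))
    t_central = _first_crossing(
        grid, intercept + slope * grid, spec_limit, direction
    )
    return IchEstimate(slope, intercept, t_cross, t_central, level, n)


def ich_q1e_from_dataset(
    ds: StabilityDataset,
    storage_temp_C: float,
    spec_limit: float,
    direction: int,
    **kwargs,
) -> IchEstimate:
    """Convenience wrapper extracting the storage arm from a dataset."""
    arm = ds.arm_frame(storage_temp_C)
    if len(arm) == 0:
        raise IdentifiabilityError(f"no records at {storage_temp_C} degC")
    return ich_q1e_baseline(
        arm["time_days"].to_numpy(dtype=float),
        arm["value"].to_numpy(dtype=float),
        spec_limit,
        direction,
        **kwargs,
    )


def profile_checksum(profile: TemperatureProfile) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(profile.times).tobytes())
    h.update(np.ascontiguousarray(profile.temps).tobytes())
    h.update(profile.interpolation.encode())
    return h.hexdigest()[:16]


@dataclass
class ExcursionReport:
    band: PredictionBand  # lower/upper equal central when no ensemble given
    equivalent_days_at_ref: float
    reference_temp_K: float
    checksum: str
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "equivalent_days_at_ref": self.equivalent_days_at_ref,
                "reference_temp_C": self.reference_temp_K - 273.15,
                "profile_checksum": self.checksum,
                "warnings": self.warnings,
                "level": self.band.level,
            },
            indent=2,
        )


def excursion_monitor(
    fit: FitResult,
    profile: TemperatureProfile,
    transform,
    grid,
    ensemble: BootstrapEnsemble | None = None,
    level: float = 0.95,
    reference_temp_K: float = 278.15,
    gap_threshold_days: float = 2.0,
    conc: float = 1.0,
) -> ExcursionReport:
    """Degradation trajectory (and band) under a recorded temperature trace.

    Also reports the thermal "budget" consumed: the excursion expressed as
    equivalent isothermal days at the reference storage temperature,
    ``integral k1(T(s)) ds / k1(T_ref)`` with the top model's step-1 rate
    constant (advisory for two-step fits).
    """
    grid = np.asarray(grid, dtype=float)
    warn = []
    gaps = np.diff(profile.times)
    if np.any(gaps > gap_threshold_days):
        i = int(np.argmax(gaps))
        warn.append(
            f"logger gap of {gaps[i]:.2f} d starting at t={profile.times[i]:.2f} d "
            f"exceeds {gap_threshold_days} d"
        )
    if ensemble is not None:
        band = ensemble_band(
            ensemble, fit.params, profile, transform, grid, level=level, conc=conc
        )
    else:
        curve = integrate_extent(fit.params, profile, grid, C=conc, method="fast")
        central = transform.to_value(curve.alpha)
        band = PredictionBand(grid, central, central.copy(), central.copy(), level)
    theta_end = float(theta_integral(profile, fit.params.lnA1, fit.params.Ea1, [grid[-1]])[0])
    k_ref = math.exp(fit.params.lnA1 - fit.params.Ea1 / (GAS_CONSTANT * reference_temp_K))
    eq_days = theta_end / k_ref
    return ExcursionReport(band, eq_days, reference_temp_K, profile_checksum(profile), warn)


@dataclass
class BatchComparison:
    inclusion_fraction: float
    n_obs_b: int
    delta_Ea1: float  # J/mol, fit_B - fit_A
    rate_ratio_at_ref: float  # k_B / k_A at the reference temperature
    reference_temp_C: float
    level: float
    threshold: float
    comparable: bool
    fit_b: FitResult

    def to_json(self) -> str:
        return json.dumps(
            {
                "inclusion_fraction": self.inclusion_fraction,
                "n_obs_b": self.n_obs_b,
                "delta_Ea1_J_mol": self.delta_Ea1,
                "rate_ratio_at_ref": self.rate_ratio_at_ref,
                "reference_temp_C": self.reference_temp_C,
                "level": self.level,
                "threshold": self.threshold,
                "comparable": self.comparable,
            },
            indent=2,
        )


def compare_batches(
    fit_a: FitResult,
    ensemble_a: BootstrapEnsemble,
    ds_b: StabilityDataset,
    transform,
    level: float = 0.99,
    threshold: float = 0.95,
    reference_temp_C: float = 25.0,
    fit_options: FitOptions | None = None,
) -> BatchComparison:
    """Is batch B consistent with batch A's kinetic fingerprint?

    (i) fraction of B's observations inside A's prediction-mode band at the
    matching time and temperature, (ii) deltas of Ea and of the rate constant
    at the reference temperature between independent fits, (iii) verdict
    "comparable" when the inclusion fraction reaches ``threshold``.
    """
    obs_b = to_extent(ds_b, transform)
    arms_a = np.unique(np.round(fit_a.obs.temp_K, 1))
    arms_b = np.unique(np.round(obs_b.temp_K, 1))
    common = np.intersect1d(arms_a, arms_b)
    if len(common) == 0:
        raise IdentifiabilityError("no overlapping temperature arms; comparison refused")

    inside = 0
    total = 0
    for arm in arms_b:
        sel = np.round(obs_b.temp_K, 1) == arm
        t_arm = obs_b.time_days[sel]
        y_arm = transform.to_value(obs_b.alpha[sel])
        grid = np.unique(t_arm)
        prof = TemperatureProfile.isothermal(float(arm))
        band = ensemble_band(
            ensemble_a, fit_a.params, prof, transform, grid,
            level=level, mode="prediction",
        )
        lo = np.interp(t_arm, band.times, band.lower)
        hi = np.interp(t_arm, band.times, band.upper)
        inside += int(np.sum((y_arm >= lo - 1e-12) & (y_arm <= hi + 1e-12)))
        total += len(t_arm)
    frac = inside / total

    opts = fit_options or FitOptions(seed=fit_a.seed, extra_starts=[fit_a.params])
    fit_b = fit_model(fit_a.spec, obs_b, opts)
    T_ref = celsius_to_kelvin(reference_temp_C)
    ratio = fit_b.k_at(T_ref) / fit_a.k_at(T_ref)
    return BatchComparison(
        inclusion_fraction=float(frac),
        n_obs_b=total,
        delta_Ea1=float(fit_b.params.Ea1 - fit_a.params.Ea1),
        rate_ratio_at_ref=float(ratio),
        reference_temp_C=reference_temp_C,
        level=level,
        threshold=threshold,
        comparable=bool(frac >= threshold),
        fit_b=fit_b,
    )
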