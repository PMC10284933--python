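"""Synthetic accelerated-stability scenarios.

Real product stability tables are proprietary; these generators emulate
their structure so every stage of the pipeline is testable: 3 temperature
arms (5/25/40 degC by default), 21-30 points, at least 20 % conversion at
the hottest arm, one- or two-step kinetics, additive Gaussian noise in
attribute units.  Each preset fixes a "true" model whose parameters are
returned alongside the noisy dataset for recovery tests.

Presets
-------
- ``mab-acidic-variants``  one-step nth-order growth of acidic species
- ``hmw-aggregation``      slow zero-order HMW growth (0.0046 %/day at 25 degC)
- ``decelerating-vaccine`` two-step: fast low-barrier drop then slow decline
- ``concentration-dimer``  dimerization scaling linearly with concentration (p = 1)
- ``live-attenuated-titer`` first-order infectious-titer loss, log-scale units
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import AttributeTransform, DesignReport, StabilityDataset, validate_design
from .errors import DomainError
from .integrator import extent_at_observations
from .kinetics import (
    GAS_CONSTANT,
    KineticParameters,
    ModelSpec,
    first_order_spec,
    nth_order_spec,
    two_step_spec,
    zero_order_spec,
)
from .profiles import TemperatureProfile
from .units import celsius_to_kelvin, months_to_days

DEFAULT_ARMS_C = (5.0, 25.0, 40.0)
DEFAULT_TIMES_MONTHS = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 6.0)
EXTENDED_TIMES_MONTHS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0)


def _lnA_for(k: float, Ea: float, T_K: float) -> float:
    """Pre-exponential log giving rate constant ``k`` at temperature ``T``."""
    return math.log(k) + Ea / (GAS_CONSTANT * T_K)


@dataclass
class ScenarioConfig:
    """A complete simulated study: truth, design, transform, noise."""

    name: str
    spec: ModelSpec
    params: KineticParameters
    transform: AttributeTransform
    arms_C: tuple = DEFAULT_ARMS_C
    times_months: tuple = DEFAULT_TIMES_MONTHS
    sigma: float = 0.0  # additive Gaussian noise, attribute units
    seed: int = 0
    concentrations: tuple | None = None  # mg/mL arms; None = concentration-blind

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    config: ScenarioConfig
    params: KineticParameters
    spec: ModelSpec
    noiseless: pd.DataFrame
    transform: AttributeTransform
    design_report: DesignReport = None


def generate_dataset(cfg: ScenarioConfig, seed: int | None = None):
    """Simulate one stability study; returns (dataset, ground truth).

    Values are the noiseless kinetic curves mapped to attribute units plus
    iid Gaussian noise of sd ``cfg.sigma``; deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t_days = months_to_days(np.asarray(cfg.times_months, dtype=float))
    concs = cfg.concentrations if cfg.concentrations else (None,)
    rows = []
    for conc in concs:
        for arm in cfg.arms_C:
            T = celsius_to_kelvin(arm)
            alpha = extent_at_observations(
                cfg.params, t_days, np.full_like(t_days, T),
                None if conc is None else np.full_like(t_days, conc),
            )
            y = cfg.transform.to_value(alpha)
            for t, a, val in zip(t_days, alpha, y):
                row = {"time_days": t, "temperature_C": arm, "value": val, "alpha_true": a}
                if conc is not None:
                    row["concentration_mg_ml"] = conc
                rows.append(row)
    truth_df = pd.DataFrame(rows)
    hot = truth_df[truth_df["temperature_C"] == max(cfg.arms_C)]
    early = hot[hot["time_days"] <= 0.5 * hot["time_days"].max()]
    if (early["alpha_true"] >= 0.999).any():
        warnings.warn(
            f"scenario '{cfg.name}': hottest arm saturates (alpha ~ 1) early; "
            "design carries little kinetic information", stacklevel=2,
        )
    noisy = truth_df.drop(columns=["alpha_true"]).copy()
    noisy["value"] = noisy["value"] + rng.normal(0.0, cfg.sigma, size=len(noisy))
    ds = StabilityDataset(noisy, attribute=cfg.name, direction=cfg.transform.direction)
    truth = GroundTruth(cfg, cfg.params, cfg.spec, truth_df, cfg.transform)
    truth.design_report = validate_design(
        StabilityDataset(truth_df.drop(columns=["alpha_true"]), attribute=cfg.name),
        cfg.transform,
    )
    return ds, truth


def generate_excursion_profile(
    storage_C: float,
    excursions,
    horizon_days: float,
    ramp_hours: float = 1.0,
) -> TemperatureProfile:
    """Storage at ``storage_C`` with non-overlapping excursions.

    ``excursions`` is a list of (start_day, duration_days, temp_C); each
    level change takes ``ramp_hours`` (finite ramp keeps the profile
    physical and the ODE well-behaved).
    """
    ramp = ramp_hours / 24.0
    knots = [(0.0, storage_C)]
    prev_end = 0.0
    for (start, dur, temp) in sorted(excursions, key=lambda e: e[0]):
        if start <= prev_end:
            raise DomainError("excursions overlap (including ramp time)")
        if start + dur + ramp > horizon_days:
            raise DomainError("excursion extends beyond horizon")
        knots += [
            (start, storage_C),
            (start + ramp, temp),
            (start + dur, temp),
            (start + dur + ramp, storage_C),
        ]
        prev_end = start + dur + ramp
    knots.append((horizon_days, storage_C))
    return TemperatureProfile.from_knots_celsius(knots)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _preset_mab_acidic() -> ScenarioConfig:
    Ea = 100_000.0
    params = KineticParameters(
        lnA1=_lnA_for(0.004, Ea, 313.15), Ea1=Ea, n1=1.5, m1=0.0
    )
    tr = AttributeTransform(y0=2.0, span=50.0, direction=1)
    return ScenarioConfig(
        "mab-acidic-variants", nth_order_spec(), params, tr, sigma=0.005 * tr.span
    )


def _preset_hmw() -> ScenarioConfig:
    # zero-order growth tuned to 0.0046 %HMW/day at 25 degC (span 10 %)
    Ea = 80_000.0
    params = KineticParameters(
        lnA1=_lnA_for(0.00046, Ea, 298.15), Ea1=Ea, n1=0.0, m1=0.0
    )
    tr = AttributeTransform(y0=0.5, span=10.0, direction=1)
    return ScenarioConfig(
        "hmw-aggregation", zero_order_spec(), params, tr, sigma=0.005 * tr.span
    )


def _preset_decelerating_vaccine() -> ScenarioConfig:
    # fast low-barrier step (30 % of the span, noticeable within weeks even
    # at 5 degC) followed by a slow high-barrier decline: the biphasic
    # "initial rapid drop then gradual decrease" shape
    Ea1, Ea2 = 40_000.0, 110_000.0
    params = KineticParameters(
        lnA1=_lnA_for(0.05, Ea1, 278.15), Ea1=Ea1, n1=1.0, m1=0.0,
        lnA2=_lnA_for(5e-5, Ea2, 278.15), Ea2=Ea2, n2=1.0, m2=0.0,
        v=0.3,
    )
    tr = AttributeTransform(y0=100.0, span=100.0, direction=-1)
    return ScenarioConfig(
        "decelerating-vaccine", two_step_spec(), params, tr,
        times_months=EXTENDED_TIMES_MONTHS, sigma=0.005 * tr.span,
    )


def _preset_concentration_dimer() -> ScenarioConfig:
    # dimerization rate proportional to protein concentration (p = 1)
    Ea = 90_000.0
    params = KineticParameters(
        lnA1=_lnA_for(2e-5, Ea, 313.15), Ea1=Ea, n1=1.0, m1=0.0, p1=1.0
    )
    tr = AttributeTransform(y0=0.3, span=8.0, direction=1)
    spec = first_order_spec().with_free("p1")
    return ScenarioConfig(
        "concentration-dimer", spec, params, tr,
        sigma=0.005 * tr.span, concentrations=(50.0, 150.0),
    )


def _preset_live_attenuated() -> ScenarioConfig:
    # first-order infectious-titer loss; attribute is log10 titer, so the
    # additive noise is log-scale (proportional on the raw titer)
    Ea = 65_000.0
    params = KineticParameters(
        lnA1=_lnA_for(3e-4, Ea, 278.15), Ea1=Ea, n1=1.0, m1=0.0
    )
    tr = AttributeTransform(y0=6.0, span=6.0, direction=-1)
    return ScenarioConfig(
        "live-attenuated-titer", first_order_spec(), params, tr, sigma=0.005 * tr.span
    )


_PRESETS = {
    "mab-acidic-variants": _preset_mab_acidic,
    "hmw-aggregation": _preset_hmw,
    "decelerating-vaccine": _preset_decelerating_vaccine,
    "concentration-dimer": _preset_concentration_dimer,
    "live-attenuated-titer": _preset_live_attenuated,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> ScenarioConfig:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset '{name}'; available: {', '.join(preset_names())}"
        ) from None


#: presets whose truth is a single step (used by recovery studies)
ONE_STEP_PRESETS = ("mab-acidic-variants", "hmw-aggregation", "live-attenuated-titer")
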