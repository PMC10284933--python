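"""Catalog screening, information-criteria weights and the multiple-model
bootstrap (MMB).

Screening fits every catalog entry and turns the small-sample-corrected
criteria into normalized weights,

    w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2),   Delta_i = AICc_i - min AICc

(BIC weights analogously), combined as the arithmetic mean
``wCombined = (wAIC + wBIC)/2``.  When the criteria disagree, the bootstrap
loop budget ``B`` is split across models proportionally to ``wCombined``
(largest-remainder rounding), so each loop resamples residuals, refits its
assigned model, and contributes one parameter draw.  The pointwise quantiles
of the ensemble's predicted trajectories form the predictive band.

Band semantics: the default band is a *confidence* band on the mean
trajectory (quantiles of re-fitted central curves).  ``mode="prediction"``
additionally adds resampled residual noise to each loop's curve, widening it
into a band for future single observations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExtentObservations
from .errors import ConvergenceError, DesignError
from .fitting import FitOptions, FitResult, fit_model
from .integrator import integrate_extent
from .kinetics import KineticParameters, ModelCatalog, ModelSpec
from .profiles import TemperatureProfile

__all__ = [
    "ModelRanking",
    "BootstrapEnsemble",
    "PredictionBand",
    "screen_models",
    "akaike_weights",
    "allocate_loops",
    "residual_bootstrap",
    "ensemble_band",
]


def akaike_weights(criteria) -> np.ndarray:
    """exp(-Delta/2) normalized to 1, Delta relative to the best (lowest)."""
    c = np.asarray(criteria, dtype=float)
    delta = c - c.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelRanking:
    """Converged fits sorted by combined weight (descending)."""

    results: list  # FitResult, sorted
    waic: dict
    wbic: dict
    wcombined: dict
    excluded: dict = field(default_factory=dict)  # name -> reason

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "ranking": [
                    {
                        "model": r.spec.name,
                        "k_free": r.k_free,
                        "rss": r.rss,
                        "aicc": r.aicc,
                        "bic": r.bic,
                        "wAIC": self.waic[r.spec.name],
                        "wBIC": self.wbic[r.spec.name],
                        "wCombined": self.wcombined[r.spec.name],
                        "params": r.params.as_dict(),
                    }
                    for r in self.results
                ],
                "excluded": self.excluded,
            },
            indent=2,
        )


def _warm_starts_for(spec: ModelSpec, best_one_step: KineticParameters | None):
    """Seed a more complex model from the best simpler solution found so far."""
    if best_one_step is None:
        return []
    p = best_one_step
    if spec.structure == "two-step":
        return [
            p.replace(
                v=0.95,
                lnA2=p.lnA1 - 3.0,
                Ea2=min(p.Ea1 + 30_000.0, 295_000.0),
                n2=1.0,
                m2=0.0,
            )
        ]
    return [p]


def screen_models(
    catalog: ModelCatalog,
    obs: ExtentObservations,
    options: FitOptions | None = None,
    design_report=None,
    force: bool = False,
) -> ModelRanking:
    """Fit every catalog model and rank by combined AICc/BIC weight.

    ``design_report`` (from :func:`stabkin.data.validate_design`) gates the
    screen: a failing design aborts unless ``force`` is set.  Ties in
    wCombined break toward fewer free parameters.
    """
    if design_report is not None and design_report.status == "fail" and not force:
        raise DesignError(
            "study design fails good-modeling-practice rules: "
            + "; ".join(design_report.reasons())
        )
    if design_report is not None and design_report.status == "fail":
        warnings.warn("design failure overridden with force=True", stacklevel=2)
    options = options or FitOptions()
    results: list[FitResult] = []
    excluded: dict[str, str] = {}
    best_one_step: KineticParameters | None = None
    best_one_step_rss = np.inf
    for spec in catalog:
        opts = FitOptions(**{**options.__dict__,
                             "extra_starts": list(options.extra_starts)
                             + _warm_starts_for(spec, best_one_step)})
        try:
            fit = fit_model(spec, obs, opts)
        except Exception as exc:  # noqa: BLE001 - reason recorded per model
            excluded[spec.name] = f"{type(exc).__name__}: {exc}"
            continue
        results.append(fit)
        if spec.structure == "one-step" and fit.rss < best_one_step_rss:
            best_one_step, best_one_step_rss = fit.params, fit.rss
    if not results:
        raise ConvergenceError(
            "all catalog models failed: "
            + "; ".join(f"{k}: {v}" for k, v in excluded.items())
        )
    waic_arr = akaike_weights([r.aicc for r in results])
    wbic_arr = akaike_weights([r.bic for r in results])
    wcomb_arr = (waic_arr + wbic_arr) / 2.0
    waic = {r.spec.name: float(w) for r, w in zip(results, waic_arr)}
    wbic = {r.spec.name: float(w) for r, w in zip(results, wbic_arr)}
    wcomb = {r.spec.name: float(w) for r, w in zip(results, wcomb_arr)}
    order = sorted(
        results, key=lambda r: (-wcomb[r.spec.name], r.k_free, r.spec.name)
    )
    return ModelRanking(order, waic, wbic, wcomb, excluded)


def allocate_loops(ranking: ModelRanking, B: int) -> dict[str, int]:
    """Largest-remainder split of ``B`` loops proportional to wCombined."""
    if B < 1:
        raise ValueError("B must be at least 1")
    names = [r.spec.name for r in ranking.results]
    w = np.array([ranking.wcombined[n] for n in names])
    w = w / w.sum()
    raw = B * w
    base = np.floor(raw).astype(int)
    short = B - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return dict(zip(names, (int(x) for x in base)))


@dataclass
class BootstrapEnsemble:
    """Parameter draws from the multiple-model bootstrap."""

    draws: list  # (ModelSpec, KineticParameters)
    B: int
    allocation: dict
    n_failures: int
    seed: int
    #: centered residual pool of the top-ranked fit, extent units
    residual_pool: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.draws)


@dataclass
class PredictionBand:
    """Pointwise band around the central predicted trajectory."""

    times: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "central": self.central,
                "lower": self.lower,
                "upper": self.upper,
                "level": self.level,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at(self, t: float) -> tuple[float, float, float]:
        """(central, lower, upper) linearly interpolated at time t."""
        return (
            float(np.interp(t, self.times, self.central)),
            float(np.interp(t, self.times, self.lower)),
            float(np.interp(t, self.times, self.upper)),
        )


def _band_grid(profile, grid):
    """Integration always starts at the profile start, whatever grid is asked."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] > profile.start + 1e-15:
        return np.concatenate(([profile.start], grid)), slice(1, None)
    return grid, slice(None)


def _predict_draws(draws, profile, grid, transform, conc: float = 1.0) -> np.ndarray:
    """Attribute-unit trajectories of every ensemble draw; shape (B, len(grid))."""
    full, keep = _band_grid(profile, grid)
    out = np.empty((len(draws), len(grid)))
    for i, (_, params) in enumerate(draws):
        curve = integrate_extent(params, profile, full, C=conc, method="fast")
        out[i] = transform.to_value(curve.alpha[keep])
    return out


def ensemble_band(
    ensemble: BootstrapEnsemble,
    central_params: KineticParameters,
    profile: TemperatureProfile,
    transform,
    grid,
    level: float = 0.95,
    mode: str = "confidence",
    conc: float = 1.0,
    seed: int | None = None,
) -> PredictionBand:
    """Pointwise quantile band of the ensemble under an arbitrary profile.

    This single code path serves both the storage-condition band and the
    excursion monitor, so a constant profile reproduces the standard band
    exactly.
    """
    grid = np.asarray(grid, dtype=float)
    preds = _predict_draws(ensemble.draws, profile, grid, transform, conc)
    if mode == "prediction":
        if ensemble.residual_pool is None or len(ensemble.residual_pool) == 0:
            raise ValueError("prediction-mode band needs a residual pool")
        rng = np.random.default_rng(ensemble.seed + 1 if seed is None else seed)
        noise_scale = transform.span  # residual pool lives in extent units
        idx = rng.integers(0, len(ensemble.residual_pool), size=preds.shape)
        preds = preds + transform.direction * noise_scale * ensemble.residual_pool[idx]
    elif mode != "confidence":
        raise ValueError(f"unknown band mode '{mode}'")
    q_lo, q_hi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    lower = np.quantile(preds, q_lo, axis=0)
    upper = np.quantile(preds, q_hi, axis=0)
    full, keep = _band_grid(profile, grid)
    central_curve = integrate_extent(central_params, profile, full, C=conc, method="fast")
    central = transform.to_value(central_curve.alpha[keep])
    return PredictionBand(grid, central, lower, upper, level)


def residual_bootstrap(
    ranking: ModelRanking,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    target_profile: TemperatureProfile | None = None,
    grid=None,
    transform=None,
    mode: str = "confidence",
    parametric: bool = False,
    max_failure_fraction: float = 0.20,
    conc: float = 1.0,
) -> tuple[BootstrapEnsemble, PredictionBand | None]:
    """Multiple-model residual bootstrap; optionally a band at a profile.

    Each loop resamples the assigned model's centered residuals with
    replacement (or draws Gaussian noise with matching spread when
    ``parametric``), adds them to that model's fitted values, refits from a
    warm start, and stores the parameters.  Deterministic given ``seed``.
    Aborts when more than ``max_failure_fraction`` of loops fail to refit.
    """
    if B < 100:
        warnings.warn(f"B={B} loops is low for quantile bands; consider B >= 100", stacklevel=2)
    allocation = allocate_loops(ranking, B)
    rng = np.random.default_rng(seed)
    draws = []
    n_fail = 0
    transform = transform if transform is not None else (
        ranking.best.obs.transform if ranking.best.obs is not None else None
    )
    for fit0 in ranking.results:
        n_loops = allocation.get(fit0.spec.name, 0)
        if n_loops == 0:
            continue
        obs0 = fit0.obs
        centered = fit0.residuals - fit0.residuals.mean()
        sigma = float(centered.std(ddof=1)) if len(centered) > 1 else 0.0
        warm = FitOptions(n_starts=0, seed=seed, extra_starts=[fit0.params])
        for _ in range(n_loops):
            if parametric:
                noise = rng.normal(0.0, sigma, size=len(obs0))
            else:
                noise = centered[rng.integers(0, len(centered), size=len(obs0))]
            alpha_star = fit0.fitted_alpha + noise
            obs_star = ExtentObservations(
                obs0.time_days, obs0.temp_K, alpha_star, obs0.conc, obs0.transform
            )
            try:
                refit = fit_model(fit0.spec, obs_star, warm)
            except Exception:  # noqa: BLE001 - counted, thresholded below
                n_fail += 1
                continue
            draws.append((fit0.spec, refit.params))
    if n_fail > max_failure_fraction * B:
        raise ConvergenceError(
            f"{n_fail}/{B} bootstrap loops failed to converge; band would be unreliable"
        )
    pool = ranking.best.residuals - ranking.best.residuals.mean()
    ensemble = BootstrapEnsemble(draws, B, allocation, n_fail, seed, residual_pool=pool)
    band = None
    if target_profile is not None:
        if grid is None or transform is None:
            raise ValueError("band output needs target grid and transform")
        band = ensemble_band(
            ensemble, ranking.best.params, target_profile, transform, grid,
            level=level, mode=mode, conc=conc,
        )
    return ensemble, band
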