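"""Stability-study tables, attribute <-> extent mapping and design validation.

A stability dataset is one record per (time, incubation temperature,
measured value), optionally with protein concentration and batch label.
The rate law is written in the degradation extent ``alpha``; the
:class:`AttributeTransform` maps a measured attribute (HMW %, potency, titer,
fluorescence, ...) onto ``alpha`` via baseline ``y0``, total conversion
``span`` and a ``direction`` (+1 if the attribute grows as the product
degrades, -1 if it falls).

The design validator implements the good-modeling-practice entry rules:
at least three incubation temperatures, 20 points (30 to avoid a warning),
and at least 20 % conversion reached at the hottest arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError
from .units import celsius_to_kelvin, months_to_days

REQUIRED_COLUMNS = ("time_days", "temperature_C", "value")


@dataclass(frozen=True)
class AttributeTransform:
    """Linear map between attribute units and degradation extent.

    ``alpha = direction * (y - y0) / span``;
    ``y = y0 + direction * span * alpha``.
    """

    y0: float
    span: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise DomainError("transform span must be positive")
        if self.direction not in (1, -1):
            raise DomainError("direction must be +1 or -1")

    def to_extent(self, y):
        return self.direction * (np.asarray(y, dtype=float) - self.y0) / self.span

    def to_value(self, alpha):
        return self.y0 + self.direction * self.span * np.asarray(alpha, dtype=float)


@dataclass
class StabilityDataset:
    """Accelerated-stability records plus attribute metadata."""

    frame: pd.DataFrame
    attribute: str = "attribute"
    units: str = ""
    direction: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset missing required columns: {missing}")
        if (self.frame["time_days"] < 0).any():
            bad = self.frame.index[self.frame["time_days"] < 0][0]
            raise SchemaError(f"negative time at row {bad}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_points(self) -> int:
        return len(self.frame)

    def arms(self) -> np.ndarray:
        """Distinct incubation temperatures (degC), rounded to 0.1 degC."""
        return np.unique(np.round(self.frame["temperature_C"].to_numpy(dtype=float), 1))

    def arm_frame(self, temp_C: float) -> pd.DataFrame:
        sel = np.round(self.frame["temperature_C"].to_numpy(dtype=float), 1) == round(temp_C, 1)
        return self.frame[sel]

    def baseline_value(self) -> float:
        """Mean of the earliest-time records (time-zero replicates)."""
        t = self.frame["time_days"].to_numpy(dtype=float)
        return float(self.frame["value"][t == t.min()].mean())

    def concentrations(self) -> np.ndarray:
        if "concentration_mg_ml" not in self.frame.columns:
            return np.empty(0)
        return np.unique(self.frame["concentration_mg_ml"].dropna().to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ExtentObservations:
    """Fit-ready arrays: one isothermal-arm observation per entry."""

    time_days: np.ndarray
    temp_K: np.ndarray
    alpha: np.ndarray
    conc: np.ndarray | None = None
    transform: AttributeTransform | None = None

    def __len__(self) -> int:
        return len(self.time_days)

    def subset(self, mask) -> "ExtentObservations":
        return ExtentObservations(
            self.time_days[mask],
            self.temp_K[mask],
            self.alpha[mask],
            None if self.conc is None else self.conc[mask],
            self.transform,
        )


def read_stability_csv(path, attribute: str = "attribute", units: str = "",
                       direction: int = 1, allow_nan: bool = False) -> StabilityDataset:
    """Read the standard stability CSV.

    Required columns: ``time_days`` (or ``time_months``, converted at
    30.4375 d/month), ``temperature_C``, ``value``.  Optional:
    ``concentration_mg_ml``, ``batch``.
    """
    df = pd.read_csv(path)
    if "time_days" not in df.columns:
        if "time_months" in df.columns:
            df["time_days"] = months_to_days(pd.to_numeric(df["time_months"], errors="coerce"))
            df = df.drop(columns=["time_months"])
        else:
            raise SchemaError("stability CSV needs a 'time_days' or 'time_months' column")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"stability CSV missing required columns: {missing}")
    for col in REQUIRED_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"unparseable number in column '{col}' at row {bad[0]}: {df[col][bad[0]]!r}")
        df[col] = coerced
    if not allow_nan and df[list(REQUIRED_COLUMNS)].isna().any().any():
        row = int(df.index[df[list(REQUIRED_COLUMNS)].isna().any(axis=1)][0])
        raise SchemaError(f"missing value at row {row}; pass allow_nan=True for censored records")
    keep = list(REQUIRED_COLUMNS) + [c for c in ("concentration_mg_ml", "batch") if c in df.columns]
    return StabilityDataset(df[keep], attribute=attribute, units=units, direction=direction)


def to_extent(ds: StabilityDataset, transform: AttributeTransform) -> ExtentObservations:
    """Map measured values to extent observations (not clipped to [0, 1]).

    Noise can push observations slightly outside [0, 1]; they are retained
    as-is so least squares sees unbiased residuals.
    """
    conc = None
    if "concentration_mg_ml" in ds.frame.columns:
        conc = ds.frame["concentration_mg_ml"].to_numpy(dtype=float)
    return ExtentObservations(
        time_days=ds.frame["time_days"].to_numpy(dtype=float),
        temp_K=celsius_to_kelvin(ds.frame["temperature_C"].to_numpy(dtype=float)),
        alpha=np.asarray(transform.to_extent(ds.frame["value"].to_numpy(dtype=float))),
        conc=conc,
        transform=transform,
    )


@dataclass(frozen=True)
class DesignRules:
    """Good-modeling-practice thresholds (stage-1 defaults)."""

    min_arms: int = 3
    min_points_fail: int = 20
    min_points_warn: int = 30
    min_hot_extent: float = 0.20


@dataclass
class DesignCheck:
    rule: str
    observed: float
    threshold: float
    status: str  # "pass" | "warn" | "fail"


@dataclass
class DesignReport:
    status: str  # "pass" | "warn" | "fail"
    checks: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status != "fail"

    def reasons(self) -> list[str]:
        return [
            f"{c.rule}: observed {c.observed:g} vs threshold {c.threshold:g} -> {c.status}"
            for c in self.checks
        ]


def validate_design(
    ds: StabilityDataset,
    transform: AttributeTransform,
    rules: DesignRules = DesignRules(),
) -> DesignReport:
    """Check a study design against the good-modeling-practice rules.

    FAIL when fewer than ``min_arms`` temperature arms or fewer than
    ``min_points_fail`` records; WARN between ``min_points_fail`` and
    ``min_points_warn`` points; FAIL when the hottest arm never reaches
    ``min_hot_extent`` conversion.
    """
    if len(ds) == 0:
        raise SchemaError("empty dataset")
    checks = []
    arms = ds.arms()
    n_arms = len(arms)
    checks.append(DesignCheck(
        "temperature-arms", n_arms, rules.min_arms,
        "pass" if n_arms >= rules.min_arms else "fail",
    ))
    n = ds.n_points
    if n < rules.min_points_fail:
        pts_status = "fail"
    elif n < rules.min_points_warn:
        pts_status = "warn"
    else:
        pts_status = "pass"
    checks.append(DesignCheck("point-count", n, rules.min_points_fail, pts_status))
    hot = arms.max()
    hot_extent = float(np.max(transform.to_extent(ds.arm_frame(hot)["value"].to_numpy(dtype=float))))
    checks.append(DesignCheck(
        "hot-arm-degradation", hot_extent, rules.min_hot_extent,
        "pass" if hot_extent >= rules.min_hot_extent else "fail",
    ))
    if any(c.status == "fail" for c in checks):
        status = "fail"
    elif any(c.status == "warn" for c in checks):
        status = "warn"
    else:
        status = "pass"
    return DesignReport(status, checks)
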