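"""Temperature programs: isothermal storage, chamber steps, logger traces.

A :class:`TemperatureProfile` is a piecewise function of time defined by
knots ``(t_days, T_kelvin)``.  Between knots it either interpolates linearly
(smooth physical drift, the default) or holds the previous value
("hold", for programmed chamber steps).  Beyond the last knot the last
temperature is extrapolated as a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ProfileError, SchemaError
from .units import celsius_to_kelvin, hours_to_days, kelvin_to_celsius


@dataclass(frozen=True)
class TemperatureProfile:
    times: np.ndarray  # days, strictly increasing
    temps: np.ndarray  # Kelvin
    interpolation: str = "linear"  # "linear" | "hold"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        T = np.asarray(self.temps, dtype=float)
        if t.size < 1 or t.size != T.size:
            raise ProfileError("profile needs at least one (t, T) knot")
        if np.any(np.diff(t) <= 0):
            raise ProfileError("knot times must be strictly increasing")
        if np.any(T <= 0):
            raise ProfileError("temperatures must be positive Kelvin")
        if self.interpolation not in ("linear", "hold"):
            raise ProfileError(f"unknown interpolation '{self.interpolation}'")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temps", T)

    # -- constructors -------------------------------------------------------

    @classmethod
    def isothermal(cls, T_kelvin: float, t0: float = 0.0) -> "TemperatureProfile":
        return cls(np.array([t0]), np.array([float(T_kelvin)]))

    @classmethod
    def isothermal_celsius(cls, T_celsius: float, t0: float = 0.0) -> "TemperatureProfile":
        return cls.isothermal(celsius_to_kelvin(T_celsius), t0)

    @classmethod
    def from_knots_celsius(cls, knots, interpolation: str = "linear") -> "TemperatureProfile":
        t, T = zip(*knots)
        return cls(np.asarray(t, float), celsius_to_kelvin(np.asarray(T, float)), interpolation)

    # -- evaluation ---------------------------------------------------------

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def temperature_at(self, t):
        """Temperature (K) at time ``t`` days; vectorized.

        Times before the first knot are outside the profile's domain.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0] - 1e-12):
            raise ProfileError(
                f"query time before profile start ({self.times[0]} d)"
            )
        if self.interpolation == "linear":
            out = np.interp(t, self.times, self.temps)
        else:  # hold: previous knot's value
            idx = np.searchsorted(self.times, t, side="right") - 1
            idx = np.clip(idx, 0, len(self.times) - 1)
            out = self.temps[idx]
        return out if out.ndim else float(out)

    def segments(self, t_end: float | None = None):
        """Yield ``(t0, t1, T0, T1)`` pieces covering [start, t_end].

        Each piece is linear (or constant for hold-interpolation and for the
        constant extrapolation after the last knot).
        """
        t_end = self.end if t_end is None else float(t_end)
        pieces = []
        for i in range(len(self.times) - 1):
            a, b = self.times[i], self.times[i + 1]
            if a >= t_end:
                break
            b = min(b, t_end)
            if self.interpolation == "hold":
                pieces.append((a, b, self.temps[i], self.temps[i]))
            else:
                Tb = self.temperature_at(b)
                pieces.append((a, b, self.temps[i], Tb))
        if t_end > self.end:
            pieces.append((self.end, t_end, self.temps[-1], self.temps[-1]))
        if not pieces:  # degenerate zero-length request
            pieces.append((self.start, t_end, self.temps[0], self.temps[0]))
        return pieces

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Logger-style table: elapsed hours and degrees Celsius."""
        return pd.DataFrame(
            {"time": self.times * 24.0, "temperature_C": kelvin_to_celsius(self.temps)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def from_logger_records(
    records,
    time_unit: str = "auto",
    temp_range: tuple[float, float] = (-80.0, 80.0),
    interpolation: str = "linear",
) -> TemperatureProfile:
    """Build a profile from data-logger rows ``(time, temperature_C)``.

    ``time`` may be numeric elapsed hours or ISO-8601 timestamps
    (auto-detected; override with ``time_unit`` in {"hours", "iso"}).
    Rows are sorted and de-duplicated; identical timestamps carrying
    different temperatures are an error.
    """
    rows = list(records)
    if not rows:
        raise SchemaError("logger trace is empty")
    raw_t = [r[0] for r in rows]
    temps_c = np.asarray([float(r[1]) for r in rows], dtype=float)

    if time_unit == "auto":
        try:
            float(raw_t[0])
            time_unit = "hours"
        except (TypeError, ValueError):
            time_unit = "iso"
    if time_unit == "hours":
        try:
            t_days = hours_to_days(np.asarray([float(x) for x in raw_t], dtype=float))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"unparseable elapsed-hours value: {exc}") from None
    elif time_unit == "iso":
        stamps = pd.to_datetime(pd.Series(raw_t), errors="coerce")
        if stamps.isna().any():
            bad = int(np.where(stamps.isna())[0][0])
            raise SchemaError(f"unparseable timestamp in logger row {bad}: {raw_t[bad]!r}")
        t_days = (stamps - stamps.min()).dt.total_seconds().to_numpy() / 86400.0
    else:
        raise SchemaError(f"unknown time_unit '{time_unit}'")

    lo, hi = temp_range
    if np.any((temps_c < lo) | (temps_c > hi)):
        bad = int(np.where((temps_c < lo) | (temps_c > hi))[0][0])
        raise SchemaError(
            f"logger temperature {temps_c[bad]} degC outside physical range [{lo}, {hi}]"
        )

    order = np.argsort(t_days, kind="stable")
    t_days, temps_c = t_days[order], temps_c[order]
    keep = [0]
    for i in range(1, len(t_days)):
        if t_days[i] - t_days[keep[-1]] < 1e-12:
            if abs(temps_c[i] - temps_c[keep[-1]]) > 1e-9:
                raise SchemaError(
                    f"duplicate timestamp at t={t_days[i]:g} d with conflicting temperatures"
                )
        else:
            keep.append(i)
    t_days, temps_c = t_days[keep], temps_c[keep]
    return TemperatureProfile(t_days, celsius_to_kelvin(temps_c), interpolation)


def read_profile_csv(path, time_unit: str = "auto", **kwargs) -> TemperatureProfile:
    """Read a logger/profile CSV with columns ``time`` and ``temperature_C``."""
    df = pd.read_csv(path)
    for col in ("time", "temperature_C"):
        if col not in df.columns:
            raise SchemaError(f"profile CSV missing required column '{col}'")
    return from_logger_records(
        list(zip(df["time"], df["temperature_C"])), time_unit=time_unit, **kwargs
    )
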