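"""Soil-temperature summaries, degree-day accumulation, and the lapse model.

Degree-days are accumulated from logger traces as the time integral of the
temperature excess above the base temperature T_b, capped at the optimal
temperature T_o, over a diurnal window (08:00–18:00 by default):

    units(day) = sum over in-window readings of (min(T, T_o) - T_b)+ * dt_h / 24

with dt_h the sampling interval in hours; dividing by 24 converts °C·h to
°C·day on a calendar-day basis.  Dividing a target thermal time (°C·day)
by the mean daily units predicts the days a percentile cohort needs to
germinate in the field.

The elevational lapse model relates a temperature summary Y (°C) to
elevation x (m) through Y = a + b·x³, alongside the plain endpoint rate in
°C per 100 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import SoilTrace

__all__ = [
    "DegreeDaySummary",
    "LapseFit",
    "summarize_trace",
    "accumulate_degree_days",
    "days_to_thermal_time",
    "fit_lapse",
]


@dataclass(frozen=True)
class DegreeDaySummary:
    """Daily degree-day units accumulated between T_b and T_o."""

    daily_units: np.ndarray  # °C·day accumulated on each complete day
    mean: float
    sd: float
    window: tuple[float, float]  # (start hour, end hour)
    Tb: float
    To: float


@dataclass(frozen=True)
class LapseFit:
    """Cubic-in-elevation lapse model Y = a + b*x^3."""

    a: float  # intercept (°C)
    b: float  # cubic coefficient (°C m^-3)
    r2: float
    rate_per_100m: float  # endpoint temperature drop per 100 m elevation gain


def summarize_trace(trace: SoilTrace) -> tuple[float, float, float]:
    """Minimum, mean and maximum temperature of a trace (°C)."""
    temp = trace.temperatures
    if temp.size == 0:
        raise ValueError("empty trace")
    return float(temp.min()), float(temp.mean()), float(temp.max())


def accumulate_degree_days(
    trace: SoilTrace,
    Tb: float,
    To: float,
    window: tuple[float, float] = (8.0, 18.0),
    convention: str = "excess",
    divisor: str = "calendar_day",
) -> DegreeDaySummary:
    """Degree-days (°C·day) accumulated per day over a diurnal window.

    ``convention="excess"`` integrates (min(T, To) - Tb)+, the standard
    degree-day integrand; ``"raw_in_band"`` integrates the raw temperature
    whenever Tb <= T <= To.  ``divisor`` chooses whether °C·h are divided
    by 24 (``"calendar_day"``) or by the window length (``"window"``).
    Days with missing in-window readings are dropped.
    """
    if not Tb < To:
        raise ValueError("Tb must be below To")
    start, end = window
    if not (0.0 <= start < end <= 24.0):
        raise ValueError("window must satisfy 0 <= start < end <= 24 hours")
    if convention not in ("excess", "raw_in_band"):
        raise ValueError("convention must be 'excess' or 'raw_in_band'")
    if divisor not in ("calendar_day", "window"):
        raise ValueError("divisor must be 'calendar_day' or 'window'")
    span_minutes = trace.times[-1] - trace.times[0] + trace.interval
    if span_minutes < 1440.0:
        raise ValueError("trace must cover at least one full day")

    dt_hours = trace.interval / 60.0
    day_idx = (trace.times // 1440.0).astype(int)
    hour_of_day = (trace.times % 1440.0) / 60.0
    in_window = (hour_of_day >= start) & (hour_of_day < end)
    expected_per_day = int(round((end - start) * 60.0 / trace.interval))
    denom = 24.0 if divisor == "calendar_day" else (end - start)

    daily = []
    for day in np.unique(day_idx):
        sel = (day_idx == day) & in_window
        if int(sel.sum()) != expected_per_day:
            continue  # incomplete day, dropped
        T = trace.temperatures[sel]
        if convention == "excess":
            integrand = np.clip(np.minimum(T, To) - Tb, 0.0, None)
        else:
            integrand = np.where((T >= Tb) & (T <= To), T, 0.0)
        daily.append(float(np.sum(integrand) * dt_hours / denom))
    if not daily:
        raise ValueError("no complete day inside the requested window")
    arr = np.asarray(daily)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return DegreeDaySummary(daily_units=arr, mean=float(arr.mean()), sd=sd,
                            window=(float(start), float(end)), Tb=float(Tb), To=float(To))


def days_to_thermal_time(Tt_target: float, daily_units: float) -> float:
    """Continuous days needed to accumulate a target thermal time."""
    if daily_units <= 0:
        raise ValueError("daily degree-day units must be positive")
    if Tt_target < 0:
        raise ValueError("target thermal time must be nonnegative")
    return Tt_target / daily_units


def fit_lapse(elevations, temperatures) -> LapseFit:
    """Fit the cubic lapse model Y = a + b*x^3 and the endpoint rate.

    The endpoint rate is the temperature difference between the lowest and
    highest site divided by their elevation difference in hectometres
    (positive when temperature decreases with elevation).
    """
    x = np.asarray(elevations, dtype=float)
    y = np.asarray(temperatures, dtype=float)
    if x.size != y.size:
        raise ValueError("elevations and temperatures must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct elevations")
    res = stats.linregress(x**3, y)
    i_lo, i_hi = int(np.argmin(x)), int(np.argmax(x))
    rate = (y[i_lo] - y[i_hi]) / ((x[i_hi] - x[i_lo]) / 100.0)
    return LapseFit(a=float(res.intercept), b=float(res.slope),
                    r2=float(res.rvalue) ** 2, rate_per_100m=float(rate))
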