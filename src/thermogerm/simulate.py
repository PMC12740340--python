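"""Synthetic seed-lot generator for thermal-time germination analysis.

The generating model is the population-threshold thermal-time model: each
viable seed carries a percentile threshold g drawn uniformly on (0, 100),
and its germination rate at incubation temperature T is piecewise linear in
T with a shared base temperature T_b below the optimum and a shared ceiling
temperature T_c above it,

    GR(g, T) = (T - T_b) / theta_sub(g)        for T <= T_o,
    GR(g, T) = (T_c - T) / theta_sup(g)        for T  > T_o,

clipped at zero.  theta_sub(g) and theta_sup(g) are the suboptimal and
supraoptimal thermal times (degree-days) of the g-th percentile cohort,
linear in g around the median values so that the downstream regression of
percentile on thermal time is linear by construction.

The generator emulates a temperature-gradient incubator experiment: a fixed
number of seeds per replicate, several replicates per temperature, daily
censusing of radicle protrusion for about a month, and partial seed-lot
viability.  Soil-logger traces are emulated as a diurnal sinusoid (peak at
14:00) plus Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TimeCourse",
    "SoilTrace",
    "theta_sub",
    "theta_sup",
    "true_rate",
    "simulate_population",
    "simulate_soil_trace",
    "fixture_fatty_acids",
    "DEFAULT_TEMPERATURES",
]

#: Incubator set-points (°C) at which germination is above zero for this
#: seed lot; colder and hotter cylinders produce no germination and are
#: excluded from analysis.
DEFAULT_TEMPERATURES: tuple[float, ...] = (11.0, 14.0, 17.0, 21.0, 23.0, 25.0, 28.0, 31.0, 33.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generating thermal-time model and the assay design.

    Attributes
    ----------
    true_Tb, true_To, true_Tc:
        Base, optimal and ceiling temperatures (°C) shared by the lot.
    theta_sub50, theta_sup50:
        Median sub-/supraoptimal thermal times (°C·day).
    sub_slope, sup_slope:
        Rate of change of percentile with thermal time (% per °C·day) on
        each branch; the percentile-to-theta maps are their inverses.
    viability:
        Probability that a sown seed is able to germinate at all.
    lag_days:
        Fixed physiological lag added to every germination time (day);
        thermal-time accumulation is assumed to start immediately, so the
        default is 0.
    """

    true_Tb: float = 10.5
    true_To: float = 30.0
    true_Tc: float = 35.0
    theta_sub50: float = 60.0
    sub_slope: float = 2.5
    theta_sup50: float = 15.0
    sup_slope: float = 15.0
    viability: float = 0.9
    n_seeds: int = 50
    n_replicates: int = 5
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    census_interval: float = 1.0
    max_days: float = 30.0
    lag_days: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.true_Tb < self.true_To < self.true_Tc):
            raise ValueError("cardinal temperatures must satisfy Tb < To < Tc")
        if self.theta_sub50 <= 0 or self.theta_sup50 <= 0:
            raise ValueError("median thermal times must be positive")
        if not (0 < self.viability <= 1):
            raise ValueError("viability must be in (0, 1]")
        if self.n_seeds < 1 or self.n_replicates < 1:
            raise ValueError("n_seeds and n_replicates must be >= 1")
        if self.census_interval <= 0:
            raise ValueError("census_interval must be positive")
        if self.max_days <= 0:
            raise ValueError("max_days must be positive")
        if len(self.temperatures) == 0:
            raise ValueError("at least one incubation temperature is required")


@dataclass(frozen=True)
class TimeCourse:
    """One replicate's daily cumulative germination counts at one temperature."""

    elevation: float
    temperature: float
    replicate: str
    n_seeds: int
    counts: Mapping[int, int]  # 1-based day index -> cumulative germinated

    def __post_init__(self) -> None:
        days = list(self.counts)
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("day indices must be strictly increasing")
        vals = list(self.counts.values())
        if any(v2 < v1 for v1, v2 in zip(vals, vals[1:])):
            raise ValueError("cumulative counts must be nondecreasing")
        if vals and (min(vals) < 0 or max(vals) > self.n_seeds):
            raise ValueError("counts must lie in [0, n_seeds]")

    @property
    def days(self) -> np.ndarray:
        return np.asarray(list(self.counts), dtype=float)

    @property
    def cumulative(self) -> np.ndarray:
        return np.asarray(list(self.counts.values()), dtype=float)

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.cumulative / self.n_seeds

    @property
    def final_count(self) -> int:
        vals = list(self.counts.values())
        return vals[-1] if vals else 0

    @property
    def final_percentage(self) -> float:
        return 100.0 * self.final_count / self.n_seeds


@dataclass(frozen=True)
class SoilTrace:
    """Equally spaced soil-temperature logger readings.

    ``times`` are minutes since the start of the trace (local midnight);
    ``interval`` is the sampling interval in minutes.
    """

    times: np.ndarray
    temperatures: np.ndarray
    interval: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        temp = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", temp)
        if t.shape != temp.shape:
            raise ValueError("times and temperatures must have the same length")
        if t.size == 0:
            raise ValueError("trace must contain at least one reading")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, self.interval):
                raise ValueError("readings must be equally spaced at `interval`")
        if not np.all(np.isfinite(temp)):
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return int(self.times.size)


def theta_sub(g: float, cfg: SimulationConfig) -> float:
    """Suboptimal thermal time (°C·day) of the g-th percentile cohort."""
    return cfg.theta_sub50 + (g - 50.0) / cfg.sub_slope


def theta_sup(g: float, cfg: SimulationConfig) -> float:
    """Supraoptimal thermal time (°C·day) of the g-th percentile cohort.

    Decreasing in g: at supraoptimal temperatures the seeds with the
    largest thresholds are the first to finish, which is what makes the
    observed percentile-vs-thermal-time relation come out with slope
    +sup_slope (the empirical g-th percentile of the cumulative curve is
    the (100-g)-th threshold cohort on this branch).
    """
    return cfg.theta_sup50 - (g - 50.0) / cfg.sup_slope


def true_rate(g: float, T: float, cfg: SimulationConfig) -> float:
    """Generating germination rate (1/day) of percentile g at temperature T."""
    if not (math.isfinite(g) and math.isfinite(T)):
        raise ValueError("g and T must be finite")
    if not (0.0 < g < 100.0):
        raise ValueError("percentile g must lie in the open interval (0, 100)")
    if T <= cfg.true_To:
        th = theta_sub(g, cfg)
        if th <= 0:
            raise ValueError(f"theta_sub({g}) = {th} is not positive")
        return max(0.0, (T - cfg.true_Tb) / th)
    th = theta_sup(g, cfg)
    if th <= 0:
        raise ValueError(f"theta_sup({g}) = {th} is not positive")
    return max(0.0, (cfg.true_Tc - T) / th)


def _census_day(t: float, interval: float) -> int:
    """Census index (1-based, in units of `interval`) containing time t.

    Exact boundary times go to the later census.
    """
    return int(math.floor(t / interval)) + 1


def simulate_population(cfg: SimulationConfig, elevation: float) -> list[TimeCourse]:
    """Simulate one seed lot across the whole temperature gradient.

    Each seed is independently viable with probability ``cfg.viability``;
    each viable seed draws a percentile threshold uniformly on (0, 100) and
    germinates at continuous time ``lag_days + 1/true_rate(g, T)``, recorded
    at the daily census containing that time.  Seeds whose rate is zero or
    whose time exceeds ``max_days`` never germinate.  A single RNG stream
    seeded from the config drives every draw, replicates in deterministic
    order, so runs are reproducible byte for byte.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_census = int(math.floor(cfg.max_days / cfg.census_interval))
    # day index of the k-th census; equals the calendar day for daily censusing
    day_indices = [k + 1 for k in range(n_census)]
    out: list[TimeCourse] = []
    for T in cfg.temperatures:
        for r in range(cfg.n_replicates):
            viable = rng.random(cfg.n_seeds) < cfg.viability
            g = rng.uniform(0.0, 100.0, size=cfg.n_seeds)
            census = np.zeros(cfg.n_seeds, dtype=int)  # 0 = never germinates
            for i in range(cfg.n_seeds):
                if not viable[i]:
                    continue
                rate = true_rate(float(g[i]), float(T), cfg)
                if rate <= 0.0:
                    continue
                t_germ = cfg.lag_days + 1.0 / rate
                if t_germ > cfg.max_days:
                    continue
                k = _census_day(t_germ, cfg.census_interval)
                if k <= n_census:
                    census[i] = k
            counts = {
                day_indices[k]: int(np.count_nonzero((census > 0) & (census <= k + 1)))
                for k in range(n_census)
            }
            out.append(
                TimeCourse(
                    elevation=elevation,
                    temperature=float(T),
                    replicate=f"R{r + 1}",
                    n_seeds=cfg.n_seeds,
                    counts=counts,
                )
            )
    return out


def simulate_soil_trace(
    mean: float,
    amplitude: float,
    noise_sd: float,
    days: int,
    interval: float,
    rng_seed: int,
) -> SoilTrace:
    """Diurnal soil-temperature trace: 24 h sinusoid peaking at 14:00 + noise."""
    if days <= 0:
        raise ValueError("days must be positive")
    if interval <= 0:
        raise ValueError("interval must be positive")
    if 1440 % int(interval) != 0 or interval != int(interval):
        raise ValueError("interval (minutes) must divide 1440")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    n = int(days * 1440 / interval)
    t = np.arange(n, dtype=float) * interval
    temp = mean + amplitude * np.cos(2.0 * np.pi * (t - 14.0 * 60.0) / 1440.0)
    if noise_sd > 0:
        temp = temp + np.random.default_rng(rng_seed).normal(0.0, noise_sd, size=n)
    return SoilTrace(times=t, temperatures=temp, interval=float(interval))


def fixture_fatty_acids() -> pd.DataFrame:
    """Fatty-acid concentrations (mg/g fresh seed) for the five elevations."""
    from .biochem import fatty_acid_table

    return fatty_acid_table()
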