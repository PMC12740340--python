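"""CSV readers/writers, pipeline configuration, and the orchestrated run.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimals.  Time-course files carry one row per (elevation, temperature,
replicate, day); soil traces one row per reading; fatty-acid tables one
row per elevation.  Every writer's output is parsed losslessly by its
paired reader.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biochem, cardinal, environment, germination
from .simulate import (
    DEFAULT_TEMPERATURES,
    SimulationConfig,
    SoilTrace,
    TimeCourse,
    simulate_population,
    simulate_soil_trace,
)

__all__ = [
    "write_timecourses",
    "read_timecourses",
    "write_soil_trace",
    "read_soil_trace",
    "write_fatty_acids",
    "read_fatty_acids",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("thermogerm")

TIMECOURSE_COLUMNS = ["elevation", "temperature_C", "replicate", "n_seeds", "day", "cumulative_germinated"]
SOILTRACE_COLUMNS = ["timestamp_minutes", "temperature_C"]
FATTY_ACID_COLUMNS = ["elevation_m", "palmitic_mg_g", "linoleic_mg_g", "oleic_mg_g",
                      "stearic_mg_g", "nonadecylic_mg_g"]


# ---------------------------------------------------------------- time courses

def write_timecourses(timecourses, path) -> None:
    rows = []
    for tc in timecourses:
        for day, count in tc.counts.items():
            rows.append((tc.elevation, tc.temperature, tc.replicate, tc.n_seeds, day, count))
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


def read_timecourses(path) -> list[TimeCourse]:
    """Read and validate a time-course CSV; bad rows are reported by number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no time-course rows")
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {sorted(missing)}")
    out = []
    for (elev, temp, rep), grp in df.groupby(["elevation", "temperature_C", "replicate"], sort=True):
        grp = grp.sort_values("day")
        n_seeds = int(grp["n_seeds"].iloc[0])
        prev = -1
        for row in grp.itertuples():
            count = int(row.cumulative_germinated)
            if count < prev:
                raise ValueError(
                    f"{path}: decreasing cumulative count at file row {row.Index + 2} "
                    f"(elevation {elev}, {temp} °C, replicate {rep}, day {row.day})"
                )
            if count > n_seeds:
                raise ValueError(
                    f"{path}: count exceeds n_seeds at file row {row.Index + 2}"
                )
            prev = count
        counts = {int(r.day): int(r.cumulative_germinated) for r in grp.itertuples()}
        out.append(TimeCourse(elevation=float(elev), temperature=float(temp),
                              replicate=str(rep), n_seeds=n_seeds, counts=counts))
    return out


# ----------------------------------------------------------------- soil traces

def write_soil_trace(trace: SoilTrace, path) -> None:
    pd.DataFrame({"timestamp_minutes": trace.times,
                  "temperature_C": trace.temperatures}).to_csv(path, index=False)


def read_soil_trace(path) -> SoilTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(SOILTRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty soil trace")
    times = df["timestamp_minutes"].to_numpy(dtype=float)
    interval = float(times[1] - times[0]) if times.size > 1 else 1.0
    return SoilTrace(times=times, temperatures=df["temperature_C"].to_numpy(dtype=float),
                     interval=interval)


# ---------------------------------------------------------------- fatty acids

def write_fatty_acids(table: pd.DataFrame, path) -> None:
    df = table.reset_index()
    df.columns = FATTY_ACID_COLUMNS
    df.to_csv(path, index=False)


def read_fatty_acids(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(FATTY_ACID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {sorted(missing)}")
    df = df.set_index("elevation_m")
    df.columns = list(biochem.ACID_COLUMNS)
    return df


# -------------------------------------------------------------------- pipeline

#: Germination capacities (fraction viable) of the five elevational seed
#: lots used by the default simulation scenario.
DEFAULT_VIABILITIES = {1260: 0.78, 1660: 0.92, 2040: 0.67, 2345: 0.55, 2500: 0.58}


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    With ``simulate=True`` (default) the time courses are generated by the
    synthetic seed-lot model; otherwise ``timecourse_path`` must exist.
    """

    output_dir: str = "thermogerm_out"
    rng_seed: int = 0
    simulate: bool = True
    timecourse_path: str | None = None
    soil_trace_path: str | None = None
    fatty_acid_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    viabilities: dict = field(default_factory=lambda: dict(DEFAULT_VIABILITIES))
    alpha: float = 0.05
    degree_day_window: tuple[float, float] = (8.0, 18.0)
    degree_day_convention: str = "excess"
    soil_mean: float = 22.0
    soil_amplitude: float = 8.0
    soil_noise_sd: float = 1.5
    soil_days: int = 7
    soil_interval_minutes: float = 30.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "temperatures" in sim:
                sim["temperatures"] = tuple(sim["temperatures"])
            cfg.simulation = SimulationConfig(**sim)
        if "degree_day_window" in raw:
            cfg.degree_day_window = tuple(raw["degree_day_window"])
        if "viabilities" in raw:
            cfg.viabilities = {int(k): float(v) for k, v in raw["viabilities"].items()}
        return cfg


def _derived_seed(base: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_lot(timecourses, alpha: float = 0.05):
    """Run the thermal-time analysis on one seed lot's time courses.

    Returns (sigmoid-fits table, percentile-rates table, cardinal-estimates
    table, thermal-time regressions table).  Temperatures with zero
    germination in every replicate are excluded before fitting; fits that
    fail to converge are excluded from downstream means and logged.
    """
    by_temp: dict[float, list] = {}
    for tc in timecourses:
        by_temp.setdefault(tc.temperature, []).append(tc)
    germinating = {T: tcs for T, tcs in by_temp.items()
                   if any(tc.final_count > 0 for tc in tcs)}
    excluded = sorted(set(by_temp) - set(germinating))
    if excluded:
        log.info("excluding zero-germination temperatures: %s", excluded)
    kept = [tc for tcs in germinating.values() for tc in tcs]
    if not kept:
        raise germination.NoGerminationError("no temperature with any germination")

    scaling = germination.scale_to_max(kept)

    fit_rows = []
    fits: dict[tuple, germination.SigmoidFit] = {}
    for tc in kept:
        try:
            fit = germination.fit_sigmoid(tc)
        except germination.NoGerminationError:
            continue
        lag = germination.lag_time(tc)
        fit_rows.append({"elevation": tc.elevation, "temperature_C": tc.temperature,
                         "replicate": tc.replicate, "a": fit.a, "b": fit.b, "c": fit.c,
                         "r2": fit.r2, "lag_day": lag, "converged": fit.converged,
                         "degenerate_c": fit.degenerate_c})
        if fit.converged and not fit.degenerate_c:
            fits[(tc.elevation, tc.temperature, tc.replicate)] = fit
        else:
            log.warning("excluded sigmoid fit %s (converged=%s, degenerate=%s)",
                        fit.source, fit.converged, fit.degenerate_c)
    fits_table = pd.DataFrame(fit_rows)

    rate_rows = []
    for (elev, T, rep), fit in sorted(fits.items()):
        for g in scaling.percentiles:
            y_raw = scaling.raw_percentage(g)
            try:
                t = germination.time_to_percentile(fit, y_raw)
            except (germination.PercentileUnreachableError, ValueError):
                continue
            rate_rows.append({"elevation": elev, "percentile": g, "temperature_C": T,
                              "replicate": rep, "time_day": t,
                              "rate_per_day": germination.germination_rate(t)})
    rates_table = pd.DataFrame(rate_rows)

    card_rows = []
    if not rates_table.empty:
        for (elev, g, rep), grp in rates_table.groupby(["elevation", "percentile", "replicate"]):
            T = grp["temperature_C"].to_numpy()
            gr = grp["rate_per_day"].to_numpy()
            if T.size < 5:
                log.warning("too few temperatures for peak fit: elevation=%s g=%s rep=%s",
                            elev, g, rep)
                continue
            try:
                pf = cardinal.fit_peak(T, gr, source=(elev, g, rep))
                if not pf.converged:
                    log.warning("excluded non-converged peak fit (%s, %s, %s)", elev, g, rep)
                    continue
                est = cardinal.tangent_cardinals(pf)
            except ValueError as exc:
                log.warning("excluded peak fit (%s, %s, %s): %s", elev, g, rep, exc)
                continue
            card_rows.append({"elevation": elev, "percentile": g, "replicate": rep,
                              "Tb": est.Tb, "Tc": est.Tc, "Tt_sub": est.Tt_sub,
                              "Tt_sup": est.Tt_sup, "x_max": est.x_max,
                              "x_min": est.x_min, "r2": pf.r2})
    cardinals_table = pd.DataFrame(card_rows)

    reg_rows = []
    if not cardinals_table.empty:
        for (elev, rep), grp in cardinals_table.groupby(["elevation", "replicate"]):
            for rng_name, col in (("sub", "Tt_sub"), ("supra", "Tt_sup")):
                if len(grp) < 3:
                    continue
                try:
                    reg = cardinal.percentile_tt_regression(
                        grp["percentile"].to_numpy(), grp[col].to_numpy(), rng_name)
                except ValueError:
                    continue
                reg_rows.append({"elevation": elev, "replicate": rep, "range": rng_name,
                                 "slope_pct_per_Cday": reg.slope,
                                 "intercept_pct": reg.intercept, "r2": reg.r2, "n": reg.n})
    regressions_table = pd.DataFrame(reg_rows)
    return fits_table, rates_table, cardinals_table, regressions_table


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline and write all result tables.

    Stages: simulate (optional) -> sigmoid fits -> percentile rates ->
    peak fits and tangent cardinals -> thermal-time regressions ->
    degree-day prediction -> biochemistry summaries.  Deterministic given
    ``config.rng_seed``; any stage failure removes partially written
    outputs before re-raising with a stage tag.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("thermogerm")
    root.addHandler(handler)
    stage = "setup"

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    try:
        stage = "input"
        if config.simulate:
            timecourses = []
            for i, (elev, viability) in enumerate(sorted(config.viabilities.items())):
                cfg = dataclasses.replace(
                    config.simulation, viability=viability,
                    rng_seed=_derived_seed(config.rng_seed, i))
                timecourses.extend(simulate_population(cfg, elevation=elev))
            p = out_dir / "timecourses.csv"
            write_timecourses(timecourses, p)
            written.append(p)
        else:
            if config.timecourse_path is None or not Path(config.timecourse_path).exists():
                raise FileNotFoundError(f"time-course file not found: {config.timecourse_path}")
            timecourses = read_timecourses(config.timecourse_path)

        stage = "fits"
        by_elev: dict[float, list] = {}
        for tc in timecourses:
            by_elev.setdefault(tc.elevation, []).append(tc)
        all_fits, all_rates, all_cards, all_regs = [], [], [], []
        for elev in sorted(by_elev):
            f, r, c, g = analyze_lot(by_elev[elev], alpha=config.alpha)
            all_fits.append(f); all_rates.append(r); all_cards.append(c); all_regs.append(g)
        fits = pd.concat(all_fits, ignore_index=True)
        rates = pd.concat(all_rates, ignore_index=True)
        cards = pd.concat(all_cards, ignore_index=True)
        regs = pd.concat(all_regs, ignore_index=True)
        emit("sigmoid_fits.csv", fits)
        emit("percentile_rates.csv", rates)
        emit("cardinal_estimates.csv", cards)
        emit("tt_regressions.csv", regs)

        stage = "aggregate"
        summary = cardinal.aggregate_cardinals(cards, alpha=config.alpha)
        emit("cardinal_summary.csv", summary)

        stage = "degree_days"
        if config.soil_trace_path is not None:
            trace = read_soil_trace(config.soil_trace_path)
        else:
            trace = simulate_soil_trace(config.soil_mean, config.soil_amplitude,
                                        config.soil_noise_sd, config.soil_days,
                                        config.soil_interval_minutes,
                                        rng_seed=_derived_seed(config.rng_seed, 9999))
            p = out_dir / "soil_trace.csv"
            write_soil_trace(trace, p)
            written.append(p)
        tb = float(cards["Tb"].mean())
        to = config.simulation.true_To
        dd = environment.accumulate_degree_days(trace, tb, to,
                                                window=config.degree_day_window,
                                                convention=config.degree_day_convention)
        tt50 = float(cards.loc[cards["percentile"] == 50, "Tt_sub"].mean())
        days = environment.days_to_thermal_time(tt50, dd.mean)
        emit("degree_days.csv", pd.DataFrame([{
            "Tb_C": tb, "To_C": to, "window_start_h": dd.window[0],
            "window_end_h": dd.window[1], "daily_units_mean_Cday": dd.mean,
            "daily_units_sd_Cday": dd.sd, "Tt50_target_Cday": tt50,
            "days_to_Tt50": days}]))

        stage = "biochem"
        fa = (read_fatty_acids(config.fatty_acid_path)
              if config.fatty_acid_path is not None else biochem.fatty_acid_table())
        bio_rows = []
        for elev, row in fa.iterrows():
            prof = biochem.FattyAcidProfile(float(elev), *row.to_numpy(dtype=float))
            mg, pct = biochem.total_fatty_acids(prof)
            bio_rows.append({"elevation_m": elev, "total_mg_g": mg, "total_pct": pct,
                             "sat_unsat_ratio": biochem.sat_unsat_ratio(prof)})
        emit("biochem_summary.csv", pd.DataFrame(bio_rows))

        log.info("run complete: seed=%d, %d time courses, %d cardinal rows",
                 config.rng_seed, len(timecourses), len(cards))
        return {"sigmoid_fits": fits, "percentile_rates": rates,
                "cardinal_estimates": cards, "tt_regressions": regs,
                "cardinal_summary": summary, "biochem_summary": pd.DataFrame(bio_rows)}
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
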