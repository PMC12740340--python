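"""Cardinal temperatures and thermal times from rate–temperature curves.

The germination rate GR (1/day) of a percentile subpopulation, plotted
against incubation temperature T, is fitted with the asymmetric peak
function

    GR(T) = a * exp(-b * (T/c - 1)^2 + 1/(T - d)),        T < d,

where a is the maximal rate, b controls the width (a 1/sigma^2-like
parameter), c is the temperature of the maximal rate, and d is the
abscissa intercept of the descending limb (exp(1/(T-d)) -> 0 as T -> d-).
This particular composition of a Gaussian bump with an essential-singularity
cutoff is the unique reading of the fitted form consistent with all four
parameter meanings; it is isolated in :func:`peak_value` so an alternative
reading is a one-line change.

The cardinal temperatures are obtained geometrically: the tangent lines at
the two inflection points of the peak curve (maximum slope on the ascending
limb, minimum slope on the descending limb) are extrapolated to the
temperature axis; their intercepts are the base temperature T_b and the
ceiling temperature T_c, and the reciprocals of their slopes are the
suboptimal and supraoptimal thermal times (°C·day).  Derivatives are
numerical (central differences, step 1e-5 °C), with inflections located by
a dense grid (step 1e-3 °C) refined by bounded scalar minimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PeakFit",
    "CardinalEstimates",
    "TtRegression",
    "peak_value",
    "fit_peak",
    "inflection_points",
    "tangent_cardinals",
    "percentile_tt_regression",
    "aggregate_cardinals",
]

_DERIV_STEP = 1e-5  # °C, central-difference half-window
_GRID_STEP = 1e-3  # °C, bracketing grid for the inflection search
_EDGE_MARGIN = 0.05  # °C, keep the search away from the singularity at d


@dataclass(frozen=True)
class PeakFit:
    """Asymmetric peak fit of germination rate vs temperature (domain T < d)."""

    a: float  # maximal germination rate (1/day)
    b: float  # width parameter (dimensionless)
    c: float  # temperature of the maximal rate (°C)
    d: float  # abscissa intercept of the descending limb (°C)
    r2: float = math.nan
    source: tuple = ()
    converged: bool = True
    descending_limb_missing: bool = False
    t_data_min: float | None = None
    t_data_max: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("peak parameters a and b must be positive")
        if not self.c < self.d:
            raise ValueError("peak temperature c must lie below the intercept d")


@dataclass(frozen=True)
class CardinalEstimates:
    """Tangent-derived cardinal temperatures with their intermediates."""

    x_max: float  # ascending inflection temperature (°C)
    x_min: float  # descending inflection temperature (°C)
    y_max: float  # rate at x_max (1/day)
    y_min: float  # rate at x_min (1/day)
    slope_max: float  # dGR/dT at x_max (> 0)
    slope_min: float  # dGR/dT at x_min (< 0)
    ORD_max: float  # tangent intercept with the rate axis at x_max
    ORD_min: float  # tangent intercept with the rate axis at x_min
    Tb: float  # base temperature (°C)
    Tc: float  # ceiling temperature (°C)
    Tt_sub: float  # suboptimal thermal time, 1/slope_max (°C·day)
    Tt_sup: float  # supraoptimal thermal time, 1/|slope_min| (°C·day)


@dataclass(frozen=True)
class TtRegression:
    """Linear fit of percentile subpopulation (%) on thermal time (°C·day)."""

    slope: float  # % per °C·day
    intercept: float  # %
    r2: float
    range: str  # "sub" or "supra"
    n: int


def peak_value(fit: PeakFit, T) -> float | np.ndarray:
    """Evaluate the asymmetric peak function; defined only for T < d."""
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr >= fit.d):
        raise ValueError(f"peak function is undefined at T >= d = {fit.d} °C")
    val = fit.a * np.exp(-fit.b * (T_arr / fit.c - 1.0) ** 2 + 1.0 / (T_arr - fit.d))
    return float(val) if np.isscalar(T) else val


def _peak_model(T, a, b, c, d):
    # least-squares kernel; d is kept above the data by the fit bounds
    return a * np.exp(-b * (T / c - 1.0) ** 2 + 1.0 / np.minimum(T - d, -1e-6))


def fit_peak(temperatures: Sequence[float], rates: Sequence[float], source: tuple = ()) -> PeakFit:
    """Least-squares fit of the asymmetric peak function to (T, GR) pairs.

    Requires at least 5 points.  Initialisation: c0 at the empirical
    maximum, d0 = max(T) + 2 °C, b0 = 4, a0 matching the empirical maximum
    rate; multistart over jittered (b0, d0) pairs.  A fit whose empirical
    maximum sits at the boundary of the temperature range is flagged
    (``descending_limb_missing``) because the tangent extrapolation on the
    unsampled side is then unsupported by data.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(rates, dtype=float)
    if T.shape != y.shape:
        raise ValueError("temperatures and rates must have equal length")
    if T.size < 5:
        raise ValueError("need at least 5 (T, GR) points to fit the 4-parameter peak")
    if np.ptp(y) == 0:
        raise ValueError("all rates are equal; no peak to fit")
    order = np.argsort(T)
    T, y = T[order], y[order]

    i_max = int(np.argmax(y))
    boundary = i_max in (0, T.size - 1)
    c0 = float(T[i_max])
    t_lo, t_hi = float(T[0]), float(T[-1])
    y_max = float(np.max(y))

    # fit in (a, b, c, gap) with d = c + gap so the c < d constraint holds
    # exactly while c itself stays free; d must also clear the data range
    # (the model kernel's guard makes d <= max(T) prohibitively expensive)
    starts = []
    for b0 in (4.0, 1.0, 12.0):
        for d_off in (2.0, 5.0):
            d0 = t_hi + d_off
            a0 = y_max / math.exp(1.0 / (c0 - d0))
            starts.append((a0, b0, c0, d0 - c0))

    lo = np.array([1e-9, 1e-4, t_lo, 0.3])
    hi = np.array([50.0, 1e4, t_hi + 15.0, 40.0])

    def residuals(p):
        a, b, c, gap = p
        return _peak_model(T, a, b, c, c + gap) - y

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        res = optimize.least_squares(residuals, p0, bounds=(lo, hi),
                                     ftol=1e-14, xtol=1e-14, gtol=1e-14,
                                     max_nfev=20000)
        if not res.success:
            continue
        sse = float(np.sum(res.fun**2))
        a_f, b_f, c_f, gap_f = res.x
        if c_f + gap_f <= t_hi:  # descending intercept inside the data: invalid
            continue
        if best is None or sse < best[0] - 1e-14:
            best = (sse, np.array([a_f, b_f, c_f, c_f + gap_f]))
    if best is None:
        return PeakFit(a=y_max, b=4.0, c=c0, d=t_hi + 2.0, r2=0.0, source=source,
                       converged=False, descending_limb_missing=boundary,
                       t_data_min=t_lo, t_data_max=t_hi)
    popt = best[1]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, 1.0 - best[0] / ss_tot) if ss_tot > 0 else 1.0
    return PeakFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), d=float(popt[3]),
                   r2=r2, source=source, descending_limb_missing=boundary,
                   t_data_min=t_lo, t_data_max=t_hi)


def _derivative(fit: PeakFit, T) -> np.ndarray:
    """Central-difference first derivative of the peak function."""
    T = np.asarray(T, dtype=float)
    return (peak_value(fit, T + _DERIV_STEP) - peak_value(fit, T - _DERIV_STEP)) / (2.0 * _DERIV_STEP)


def _default_lower_bound(fit: PeakFit) -> float:
    if fit.t_data_min is not None:
        return fit.t_data_min - 5.0
    # wide enough to contain the Gaussian-limb inflection c(1 - 1/sqrt(2b))
    return fit.c - max(15.0, fit.c / math.sqrt(2.0 * fit.b) + 5.0)


def inflection_points(fit: PeakFit, lower: float | None = None) -> tuple[float, float]:
    """Temperatures of maximal (ascending) and minimal (descending) slope.

    The curve's maximum is located first; the ascending inflection x_max
    is then searched between ``lower`` (by default 5 °C below the coldest
    fitted datum) and the maximum, and the descending inflection x_min
    between the maximum and d.  Both are bracketed on a 1e-3 °C grid and
    refined by bounded minimisation of the (negated) central-difference
    derivative.  Raises if either extremum sits at a search boundary.
    """
    if lower is None:
        lower = _default_lower_bound(fit)
    upper = fit.d - _EDGE_MARGIN
    if lower >= upper:
        raise ValueError("lower search bound must lie below the descending intercept d")
    # the cutoff term can drag the function's maximum below the nominal c,
    # so bracket the inflections around the actual argmax of the curve
    grid = np.arange(lower, upper, _GRID_STEP)
    t_peak = float(grid[int(np.argmax(peak_value(fit, grid)))])
    if t_peak <= lower + _GRID_STEP or t_peak >= upper - _GRID_STEP:
        raise ValueError("curve maximum at the search boundary; no interior peak")

    def refine(t_lo: float, t_hi: float, sign: float) -> float:
        grid = np.arange(t_lo, t_hi + _GRID_STEP, _GRID_STEP)
        grid = grid[(grid > t_lo) & (grid < t_hi)]
        dvals = sign * _derivative(fit, grid)
        i = int(np.argmax(dvals))
        if i in (0, grid.size - 1):
            raise ValueError("slope extremum found at the search boundary; "
                             "widen the search interval or reject the fit")
        res = optimize.minimize_scalar(
            lambda x: -sign * float(_derivative(fit, x)),
            bounds=(float(grid[i - 1]), float(grid[i + 1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    x_max = refine(lower, t_peak, +1.0)
    x_min = refine(t_peak, upper, -1.0)
    return x_max, x_min


def tangent_cardinals(fit: PeakFit, lower: float | None = None) -> CardinalEstimates:
    """Base/ceiling temperatures and thermal times from inflection tangents.

    At each inflection point the tangent line y = ORD + slope*T is
    extrapolated to the temperature axis: T_b = -ORD_max/slope_max from the
    ascending tangent and T_c = -ORD_min/slope_min from the descending
    one.  The thermal times are the reciprocal tangent slopes, T_t,sub =
    1/slope_max and T_t,sup = 1/|slope_min|.
    """
    x_max, x_min = inflection_points(fit, lower=lower)
    y_max = peak_value(fit, x_max)
    y_min = peak_value(fit, x_min)
    slope_max = float(_derivative(fit, x_max))
    slope_min = float(_derivative(fit, x_min))
    if slope_max <= 0 or slope_min >= 0:
        raise ValueError("degenerate tangent slope at an inflection point")
    ord_max = y_max - slope_max * x_max
    ord_min = y_min - slope_min * x_min
    return CardinalEstimates(
        x_max=x_max, x_min=x_min, y_max=y_max, y_min=y_min,
        slope_max=slope_max, slope_min=slope_min,
        ORD_max=ord_max, ORD_min=ord_min,
        Tb=-ord_max / slope_max, Tc=-ord_min / slope_min,
        Tt_sub=1.0 / slope_max, Tt_sup=1.0 / abs(slope_min),
    )


def percentile_tt_regression(
    percentiles: Sequence[float], thermal_times: Sequence[float], range: str
) -> TtRegression:
    """Ordinary least squares of percentile (%) on thermal time (°C·day)."""
    if range not in ("sub", "supra"):
        raise ValueError("range must be 'sub' or 'supra'")
    g = np.asarray(percentiles, dtype=float)
    tt = np.asarray(thermal_times, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 percentiles for the regression")
    if np.ptp(tt) == 0:
        raise ValueError("thermal times are all equal; regression is degenerate")
    res = stats.linregress(tt, g)
    return TtRegression(slope=float(res.slope), intercept=float(res.intercept),
                        r2=float(res.rvalue) ** 2, range=range, n=int(g.size))


def aggregate_cardinals(estimates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± SD of per-replicate cardinal estimates, with Tukey letters.

    ``estimates`` must hold one row per replicate with columns
    ``elevation, percentile, replicate, Tb, Tc, Tt_sub, Tt_sup``.  Letters
    compare percentiles within each elevation (lower-case, per quantity
    ``Tb`` and ``Tc``); cells with fewer than 2 replicates are skipped with
    a warning.
    """
    import logging

    from .germination import compare_groups

    log = logging.getLogger(__name__)
    required = {"elevation", "percentile", "replicate", "Tb", "Tc", "Tt_sub", "Tt_sup"}
    missing = required - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table lacks columns: {sorted(missing)}")

    rows = []
    for (elev, perc), grp in estimates.groupby(["elevation", "percentile"]):
        if len(grp) < 2:
            log.warning("skipping (elevation=%s, percentile=%s): only %d replicate(s)",
                        elev, perc, len(grp))
            continue
        row = {"elevation": elev, "percentile": perc, "n": len(grp)}
        for col in ("Tb", "Tc", "Tt_sub", "Tt_sup"):
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_sd"] = float(grp[col].std(ddof=1))
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    for col in ("Tb", "Tc"):
        letters_col = []
        for elev in out["elevation"].unique():
            sub = estimates[estimates["elevation"] == elev]
            cells = sub.groupby("percentile").size()
            usable = cells[cells >= 2].index
            sub = sub[sub["percentile"].isin(usable)]
            if sub["percentile"].nunique() >= 2:
                cmpres = compare_groups(sub[col].to_numpy(), sub["percentile"].to_list(), alpha=alpha)
                lets = cmpres.letters
            else:
                lets = {p: "a" for p in usable}
            for perc in out.loc[out["elevation"] == elev, "percentile"]:
                letters_col.append((elev, perc, lets.get(perc, "")))
        mapping = {(e, p): l for e, p, l in letters_col}
        out[f"{col}_letters"] = [mapping.get((e, p), "") for e, p in zip(out["elevation"], out["percentile"])]
    return out
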