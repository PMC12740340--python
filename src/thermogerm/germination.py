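"""Fitting and inversion of cumulative germination time courses.

Cumulative germination (%) versus time t (day) is modelled with the
three-parameter logistic

    y(t) = a / (1 + b * exp(-c * t)),

where a is the asymptotic germination percentage, b > 0 positions the curve
and c > 0 (1/day) is the steepness.  The fitted curve is inverted in closed
form to obtain the time to reach each percentile subpopulation, whose
reciprocal is the germination rate used by the thermal-time model.

Percentile subpopulations are defined against the best treatment: the
maximum final percentage observed in any (temperature, replicate) of a seed
lot is taken as 100%, and deciles 10%, 20%, ... of that scaled maximum are
followed, up to the largest decile every temperature actually reached.

Group comparisons (one-way ANOVA + Tukey HSD with a compact letter display)
are provided here because every downstream table reports them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .simulate import TimeCourse

__all__ = [
    "NoGerminationError",
    "PercentileUnreachableError",
    "SigmoidFit",
    "ScalingResult",
    "GroupComparison",
    "sigmoid",
    "fit_sigmoid",
    "scale_to_max",
    "time_to_percentile",
    "germination_rate",
    "lag_time",
    "arcsine_transform",
    "compare_groups",
]


class NoGerminationError(ValueError):
    """Raised when a time course contains no germinated seed."""


class PercentileUnreachableError(ValueError):
    """Raised when a requested percentile lies at or above the fitted asymptote."""


def sigmoid(t, a, b, c):
    """Logistic cumulative-germination curve a / (1 + b e^{-c t})."""
    return a / (1.0 + b * np.exp(-c * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic fit of one replicate's cumulative germination."""

    a: float
    b: float
    c: float
    r2: float
    source: tuple  # (elevation, temperature, replicate)
    converged: bool = True
    degenerate_c: bool = False


@dataclass(frozen=True)
class ScalingResult:
    """Percentile scaling of a seed lot against its best treatment."""

    factor: float  # multiply raw % by this to get scaled %
    max_observed_final: float  # raw %, over all temperatures and replicates
    percentiles: tuple[int, ...]  # available scaled deciles, e.g. (10, ..., 60)

    def raw_percentage(self, scaled_percentile: float) -> float:
        """Raw germination % corresponding to a scaled percentile."""
        return scaled_percentile / self.factor


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def _initial_sigmoid_params(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a0 = float(np.max(y))
    # c0 from the log-slope between the 25% and 75% crossings of a0
    t25 = t[np.argmax(y >= 0.25 * a0)]
    t75 = t[np.argmax(y >= 0.75 * a0)]
    c0 = math.log(9.0) / (t75 - t25) if t75 > t25 else 0.5
    # b0 from the first positive observation
    i1 = int(np.argmax(y > 0))
    y1 = float(y[i1])
    b0 = max((a0 * 1.02 / y1 - 1.0) * math.exp(c0 * float(t[i1])), 1e-6)
    return a0, b0, c0


def fit_sigmoid(timecourse: TimeCourse) -> SigmoidFit:
    """Least-squares logistic fit of cumulative germination % vs day.

    Raises :class:`NoGerminationError` for an all-zero time course.  A
    saturated course (constant nonzero counts from the first census) has no
    identifiable steepness and is returned with ``degenerate_c=True``; a
    fit that fails to converge after three jittered restarts is returned
    flagged ``converged=False`` so callers can exclude it from means.
    """
    t = timecourse.days
    y = timecourse.percentages
    if len(t) < 4:
        raise ValueError("need at least 4 census points to fit the sigmoid")
    if timecourse.final_count == 0:
        raise NoGerminationError(
            f"no germination at {timecourse.temperature} °C, replicate "
            f"{timecourse.replicate} (elevation {timecourse.elevation} m)"
        )
    source = (timecourse.elevation, timecourse.temperature, timecourse.replicate)
    if np.all(y == y[0]):
        # saturated from day 1: asymptote is observed, steepness unidentifiable
        return SigmoidFit(a=float(y[0]), b=math.nan, c=math.nan, r2=1.0,
                          source=source, converged=True, degenerate_c=True)

    a0, b0, c0 = _initial_sigmoid_params(t, y)
    rng = np.random.default_rng(12345)
    best = None
    for k in range(3):
        if k == 0:
            p0 = (a0, b0, c0)
        else:
            jit = rng.uniform(0.7, 1.3, size=3)
            p0 = (a0 * jit[0], b0 * jit[1], c0 * jit[2])
        try:
            popt, _ = optimize.curve_fit(
                sigmoid, t, y, p0=p0,
                bounds=([1e-9, 1e-9, 1e-9], [200.0, 1e9, 50.0]),
                ftol=1e-12, xtol=1e-12, gtol=1e-12, maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - sigmoid(t, *popt)) ** 2))
        if best is None or sse < best[0] - 1e-10:
            best = (sse, popt)
    if best is None:
        return SigmoidFit(a=a0, b=b0, c=c0, r2=0.0, source=source, converged=False)
    popt = best[1]
    r2 = _r2(y, sigmoid(t, *popt))
    return SigmoidFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                      r2=r2, source=source)


def scale_to_max(timecourses: Sequence[TimeCourse]) -> ScalingResult:
    """Scale a seed lot's percentages against its best treatment.

    The maximum final percentage over all temperatures and replicates is
    taken as 100%.  The available percentile subpopulations are the deciles
    {10, 20, ...} up to the largest decile not exceeding the minimum (over
    temperatures with any germination) of the mean scaled final percentage,
    capped at 80.
    """
    if len(timecourses) == 0:
        raise ValueError("empty time-course set")
    finals = np.array([tc.final_percentage for tc in timecourses])
    if np.all(finals == 0):
        raise NoGerminationError("no germination in any treatment of the set")
    max_final = float(np.max(finals))
    factor = 100.0 / max_final

    per_temp: dict[float, list[float]] = {}
    for tc in timecourses:
        per_temp.setdefault(tc.temperature, []).append(tc.final_percentage)
    temp_means = {T: float(np.mean(v)) for T, v in per_temp.items()}
    germinating = [m for m in temp_means.values() if m > 0]
    min_scaled = min(germinating) * factor
    top = min(80, int(min_scaled // 10) * 10)
    percentiles = tuple(range(10, top + 10, 10))
    return ScalingResult(factor=factor, max_observed_final=max_final, percentiles=percentiles)


def time_to_percentile(fit: SigmoidFit, y: float) -> float:
    """Closed-form inversion of the logistic: day at which raw % y is reached.

    t = -ln((a/y - 1)/b) / c.  Raises for y outside (0, a) and for times
    at or before sowing (y below the fitted intercept).
    """
    if y <= 0:
        raise ValueError("percentage must be positive")
    if y >= fit.a:
        raise PercentileUnreachableError(
            f"{y:.3f}% is at or above the fitted asymptote a={fit.a:.3f}%"
        )
    if not (math.isfinite(fit.b) and math.isfinite(fit.c)) or fit.c <= 0:
        raise ValueError("fit has no identifiable steepness")
    t = -math.log((fit.a / y - 1.0) / fit.b) / fit.c
    if t < 0:
        raise ValueError(f"percentage {y:.3f}% lies below the fitted intercept (t={t:.3f})")
    return t


def germination_rate(t: float) -> float:
    """Germination rate (1/day): the reciprocal of the time to a percentile."""
    if t <= 0:
        raise ValueError("time must be positive")
    return 1.0 / t


def lag_time(timecourse: TimeCourse) -> int | None:
    """First census day with any germination; None if nothing germinated."""
    for day, count in timecourse.counts.items():
        if count > 0:
            return day
    return None


def arcsine_transform(p: float) -> float:
    """Arcsine square-root transform of a percentage: arcsin(sqrt(p/100))."""
    if not 0.0 <= p <= 100.0:
        raise ValueError("percentage must be in [0, 100]")
    return math.asin(math.sqrt(p / 100.0))


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc and compact letter display."""

    f_statistic: float
    p_value: float
    alpha: float
    letters: dict  # group label -> letter string; shared letter = not different
    group_means: dict


def _compact_letter_display(groups: list, distinct: set[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    ``distinct`` holds unordered pairs of group labels that are
    significantly different; groups sharing a letter are not.
    """
    letter_sets: list[set] = [set(groups)]
    for g1, g2 in distinct:
        for s in list(letter_sets):
            if g1 in s and g2 in s:
                letter_sets.remove(s)
                s1 = s - {g2}
                s2 = s - {g1}
                for cand in (s1, s2):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    # absorb: drop sets contained in another
    letter_sets = [s for s in letter_sets
                   if not any(s < other for other in letter_sets)]
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_groups(values: Sequence[float], groups: Sequence, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Returns the F statistic, its p value, and a compact letter display in
    which groups sharing a letter are not significantly different at
    ``alpha``.  Groups with identical values everywhere (zero variance,
    equal means) collapse to a single letter.
    """
    values = np.asarray(values, dtype=float)
    labels = list(groups)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    by_group = {g: values[[i for i, lb in enumerate(labels) if lb == g]] for g in uniq}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("need at least two values per group")
    means = {g: float(np.mean(v)) for g, v in by_group.items()}

    if all(np.ptp(v) == 0 for v in by_group.values()) and len({round(m, 12) for m in means.values()}) == 1:
        # fully degenerate: identical data everywhere
        return GroupComparison(math.nan, 1.0, alpha, {g: "a" for g in uniq}, means)

    f_stat, p = stats.f_oneway(*(by_group[g] for g in uniq))

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, np.asarray(labels, dtype=object), alpha=alpha)
    distinct: set[tuple] = set()
    from itertools import combinations

    for (g1, g2), reject in zip(combinations(tk.groupsunique, 2), tk.reject):
        if bool(reject):
            distinct.add((g1, g2))
    letters = _compact_letter_display(uniq, distinct)
    return GroupComparison(float(f_stat), float(p), alpha, letters, means)
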