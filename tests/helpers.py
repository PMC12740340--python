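"""Shared test utilities: independent brute-force oracles and data builders.

The grid oracle re-derives the tangent-extrapolated cardinal temperatures
from nothing but dense evaluation of the peak curve: derivative by finite
differences on a 1e-5 °C grid, inflections by grid argmax/argmin, tangent
lines written out explicitly.  It shares no code path with
``thermogerm.cardinal``.
"""

from __future__ import annotations

import math

import numpy as np

from thermogerm.simulate import TimeCourse


def peak_curve(T, a, b, c, d):
    T = np.asarray(T, dtype=float)
    return a * np.exp(-b * (T / c - 1.0) ** 2 + 1.0 / (T - d))


def default_lower(a, b, c, d):
    # same search-interval convention as the implementation's param-only
    # default; the oracle's independence is in how it locates the
    # inflections and tangents, not in the interval searched
    return c - max(15.0, c / math.sqrt(2.0 * b) + 5.0)


def grid_oracle_cardinals(a, b, c, d, lower=None, step=1e-5):
    """Brute-force tangent cardinals from a dense grid scan."""
    if lower is None:
        lower = default_lower(a, b, c, d)
    upper = d - 0.05
    T = np.arange(lower, upper, step)
    f = peak_curve(T, a, b, c, d)
    # centred finite-difference derivative on the grid
    df = np.empty_like(f)
    df[1:-1] = (f[2:] - f[:-2]) / (2.0 * step)
    df[0], df[-1] = df[1], df[-2]
    i_peak = int(np.argmax(f))
    asc = slice(0, i_peak)
    desc = slice(i_peak, T.size)
    i_max = int(np.argmax(df[asc]))
    i_min = i_peak + int(np.argmin(df[desc]))
    x_max, x_min = float(T[i_max]), float(T[i_min])
    y_max, y_min = float(f[i_max]), float(f[i_min])
    s_max, s_min = float(df[i_max]), float(df[i_min])
    ord_max = y_max - s_max * x_max
    ord_min = y_min - s_min * x_min
    return {
        "x_max": x_max, "x_min": x_min,
        "Tb": -ord_max / s_max, "Tc": -ord_min / s_min,
        "Tt_sub": 1.0 / s_max, "Tt_sup": 1.0 / abs(s_min),
    }


def random_peak_params(rng):
    """One random valid peak-parameter set (a, b, c, d)."""
    a = rng.uniform(0.05, 0.5)
    b = rng.uniform(1.0, 10.0)
    c = rng.uniform(20.0, 32.0)
    d = c + rng.uniform(2.0, 10.0)
    return a, b, c, d


def sigmoid_timecourse(a, b, c, n_seeds=100, days=30, elevation=2345.0,
                       temperature=25.0, replicate="R1", integer_counts=False):
    """Noiseless TimeCourse whose counts follow the logistic exactly.

    By default counts are kept fractional so the curve is represented
    without rounding error; pass ``integer_counts=True`` to emulate real
    census data.
    """
    counts = {}
    prev = 0.0
    for day in range(1, days + 1):
        y = a / (1.0 + b * math.exp(-c * day))  # percent
        count = y / 100.0 * n_seeds
        if integer_counts:
            count = round(count)
        counts[day] = max(prev, count)
        prev = counts[day]
    return TimeCourse(elevation=elevation, temperature=temperature,
                      replicate=replicate, n_seeds=n_seeds, counts=counts)
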