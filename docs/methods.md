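# Methods

## The thermal-time framework

Seed lots are modelled as populations of percentile cohorts. At a
suboptimal constant temperature T (between the base temperature T_b and
the optimum T_o) the g-th percentile cohort germinates once it accumulates
its suboptimal thermal time θ_sub(g) (°C·day), so its germination rate is
GR = (T − T_b)/θ_sub(g); at supraoptimal temperatures (T_o < T < T_c) the
rate is GR = (T_c − T)/θ_sup(g). T_b and T_c are shared by the lot;
θ varies across percentiles, linearly by assumption, which is what makes
the regression of percentile on thermal time a straight line whose slope
(% per °C·day) summarises within-lot heterogeneity.

The estimation pipeline does not assume that generating model. It follows
the classical empirical route:

1. **Logistic time-course fit.** Cumulative germination (%) vs day is
   fitted per replicate with y = a/(1 + b·e^(−ct)) by nonlinear least
   squares (three jittered starts; initial a₀ = max observed %, c₀ from
   the log-slope between the 25% and 75% crossings, b₀ from the first
   positive observation). All-zero courses raise; saturated courses
   (constant counts from day 1) have no identifiable steepness and are
   flagged and excluded from downstream means, as are non-converged fits.
   Temperatures with zero germination in every replicate are excluded
   before fitting.
2. **Percentile scaling.** The maximum final percentage over all
   temperatures and replicates of a lot is taken as 100%. Percentile
   subpopulations are the deciles 10…80, available up to the largest
   decile not exceeding the minimum (over germinating temperatures) of
   the mean scaled final percentage — the floor-to-decile reading of
   "enough percentiles at every temperature".
3. **Inversion and rates.** t(y) = −ln((a/y − 1)/b)/c, GR = 1/t.
   Percentiles at or above a replicate's fitted asymptote, or below its
   intercept, are skipped for that replicate.
4. **Peak fit per percentile and replicate.** GR vs T is fitted with
   GR(T) = a·exp(−b·(T/c − 1)² + 1/(T − d)). This composition — Gaussian
   bump times an essential-singularity cutoff — is the unique reading of
   the asymmetric peak form consistent with a = maximal rate, c = peak
   temperature, d = descending abscissa intercept (e^{1/(T−d)} → 0 as
   T → d⁻). It is isolated in one function (`peak_value`) so an
   alternative reading is a one-line change. The fit is parameterised as
   (a, b, c, gap) with d = c + gap, which enforces c < d exactly while
   leaving c free; fits whose descending intercept lands inside the data
   range are rejected, and fits whose empirical maximum sits at the edge
   of the temperature ladder are flagged (`descending_limb_missing`).
5. **Tangent extraction.** Derivatives are central differences with step
   1e-5 °C (numerical on purpose: robust to swapping the functional
   form). The curve's maximum is located first; the two inflection points
   are then the argmax/argmin of the derivative on either side of it,
   bracketed on a 1e-3 °C grid and refined by bounded scalar
   minimisation. The tangent lines there give T_b = −ORD_max/slope_max,
   T_c = −ORD_min/slope_min (ORD = y − slope·x), θ_sub = 1/slope_max, and
   θ_sup = 1/|slope_min|. The ascending search extends 5 °C below the
   coldest fitted datum (or, for parameter-only fits, far enough to
   contain the Gaussian-limb inflection). A flat derivative extremum
   limits the locator to about 1e-5 °C, which is far below every
   scientific tolerance used here.
6. **Aggregation.** Per-replicate estimates are averaged to mean ± SD
   (n = number of replicates), with one-way ANOVA + Tukey HSD compact
   letters comparing percentiles within an elevation. The letter display
   uses the standard insert-and-absorb algorithm at α = 0.05.

An independent brute-force oracle (dense 1e-5 °C grid, finite-difference
derivative, explicit tangent algebra; `tests/helpers.py`) checks the
tangent extraction to 0.05 °C on T_b/T_c and 1% on θ over random
parameter sets.

## Degree-days and field prediction

Soil traces are summarised (min/mean/max) and accumulated per calendar
day over a diurnal window (default 08:00–18:00) as
Σ (min(T, T_o) − T_b)⁺ · Δt_h / 24, i.e. the standard degree-day
integrand, converted from °C·h to °C·day by the calendar day. This is the
convention under which accumulated units are commensurable with the
tangent-derived thermal times. Two documented alternatives sit behind
flags: integrating the raw temperature whenever it lies in [T_b, T_o]
(`convention="raw_in_band"`), and dividing by the window length instead
of 24 h (`divisor="window"`). Readings are weighted by their full
sampling interval (left-closed); days with missing in-window readings are
dropped, not imputed. Days to a target thermal time are the plain
quotient target/mean-daily-units. The elevational lapse model is ordinary
least squares of a temperature summary on elevation cubed,
Y = a + b·x³, reported with the endpoint rate in °C per 100 m.

## The synthetic generator

`simulate_population` draws, per replicate, n_seeds independent seeds:
viable with probability `viability`, each viable seed with a percentile
threshold g ~ U(0, 100) and germination time lag + 1/GR(g, T) under the
generating model above, recorded at the daily census containing that time
(census day = ⌊t⌋ + 1: the ceiling for non-integer times, with exact
boundary times going to the later census). Seeds with zero rate or times
beyond the one-month observation window never germinate. One RNG stream
per simulation, seeded from the config, with replicates drawn in a fixed
order, makes runs byte-reproducible. Soil traces are a 24 h sinusoid
peaking at 14:00 plus i.i.d. Gaussian noise.

Default scenario (one seed lot): T_b = 10.5 °C, T_c = 35 °C,
θ_sub(50) = 60 °C·day with the percentile relation changing at
2.5 %/(°C·day); nine incubation temperatures 11–33 °C, 5 replicates of 50
seeds, 90% viability (the five-elevation pipeline uses the lot-specific
capacities 78/92/67/55/58%). The generating optimum is set to
T_o = 30 °C — inside the empirically typical 28–31 °C window — and
θ_sup(50) = 15 °C·day is chosen so the median rate curve is continuous at
the optimum ((30 − 10.5)/60 ≈ (35 − 30)/15). A larger supraoptimal
percentile sensitivity (15 %/(°C·day)) encodes the observation that the
ceiling is nearly constant across percentiles. Note that the *estimated*
θ_sup that the tangent method returns from such data is much smaller than
the generative 15 °C·day (≈5 °C·day in the worked example): the tangent
at a sharp descending inflection is steeper than the generating secant.
Published supraoptimal thermal times of a few °C·day are therefore
estimator outputs, not generative secants, and the generator does not use
them as defaults.

What the generator does **not** emulate: dormancy and its loss, water
stress (no hydrothermal-time axis), seed-to-seed lag variation (the lag
offset is a single constant, default 0), overdispersion beyond binomial
viability, and any correlation between viability and thermal
parameters. Passing recovery tests therefore show that the estimation
pipeline inverts *this* data-generating process at realistic sample
sizes — not that real seed lots satisfy its assumptions.

## Known estimator bias

The tangent-to-peak-function estimator is biased relative to the
piecewise-linear generating truth, and the bias survives at zero noise:
feeding exact generating rates for the default scenario into the peak fit
returns T_b ≈ 12.0 °C (true 10.5) and T_c ≈ 33.7 °C (true 35.0), while
θ_sub(50) is recovered to about −12%. Two mechanisms: (i) nothing
constrains the fitted descending intercept d between the hottest datum
(33 °C) and the true ceiling, and least squares prefers a sharp cutoff
just above 33 °C, pulling T_c low; (ii) the Gaussian limb fitted to a
near-linear ascending ramp bends, so the steepest tangent is steeper than
the ramp, placing its axis intercept above the true base and its
reciprocal slope below the true θ. Consistent with this, the estimated
ceiling varies far less across percentiles than the estimated base (the
near-constant-ceiling pattern), and full-simulation recovery
(10 independent lots) lands at T_b ≈ 12.07, T_c ≈ 33.76,
θ_sub(50) ≈ 53 °C·day. Users comparing lots should rely on *differences*
between lots estimated with the same temperature ladder, which share the
bias, rather than on absolute cardinal values.

## Problem sizes and numerics

Test and demonstration runs use 5 replicates × 50 seeds on the 9-(really
8 germinating)-temperature ladder, 10 independent lots for recovery
statistics, 50 random parameter sets for the oracle comparison, and
week-long half-hourly soil traces; these sizes give Monte-Carlo error
well below the scientific tolerances while keeping any run at the scale
of seconds to a couple of minutes. Nonlinear fits use least squares with
ftol/xtol/gtol at 1e-12…1e-14 and multistart (3 jittered starts for the
logistic, 6 (b₀, d₀) combinations for the peak); non-convergence is
flagged, logged with its (elevation, percentile/temperature, replicate)
key, and excluded from means rather than silently propagated.
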