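# Methods

## Detection model

A transect is an ordered set of plots (position 1 = lowest) with one
temperature per plot per hour, obtained by averaging the plot's available
sensors. At each transect-hour two detectors run side by side:

- **SLR/ISLR**: ordinary least-squares slope of temperature on elevation
  across the plots reporting at that hour. Strict positivity defines
  presence; strength is the slope × 100 (°C 100 m⁻¹). The slope is computed
  in closed form (centered normal equations), vectorised over all hours of
  a transect; with two points it reduces to the two-point slope, and with
  all elevations equal it is undefined and the timestep is not evaluable
  for this method.
- **Endpoint**: presence iff T(last plot) > T(first plot), strictly.
  Endpoints are fixed by *position*, not elevation rank, so elevation ties
  among interior or low plots (GPS-scale error) do not affect it. The
  timestep is not evaluable when either endpoint is missing.

Ties (flat profiles, equal endpoints) count as no inversion under both
methods — the conservative reading of strict inequality. Non-evaluable
timesteps are excluded from both numerator and denominator of every
frequency, so a frequency is always a proportion of observed, analyzable
hours; an empty period is reported as missing, never as 0%.

Reported summaries default to the endpoint method, the more conservative of
the two; a switch selects the ISLR method throughout. Strength and
temperature-difference means are taken over the timesteps the *selected*
method flags. At an endpoint-flagged hour with a non-monotone profile the
regression slope can be non-positive; the slope value is reported as-is
rather than censored, keeping the strength series faithful to the fitted
gradient.

## Aggregation conventions

- Seasons are the study calendar (late summer 2021: Aug 21–Sep 24; fall:
  Sep 25–Dec 21; winter: Dec 22–Mar 12; spring: Mar 13–Jun 7), with
  boundary days inclusive on both ends — the printed ranges abut, and the
  inclusive convention assigns every day to exactly one season.
- Hour-of-day frequencies are percentages of *dates* (one timestep per
  date-hour) and are restricted by default to the shared fall–winter window
  (Sep 25–Mar 12) so transects are compared over identical dates.
- Site-level values are unweighted means of transect-level values ± 1 SE
  (n−1 denominator), never pooled-timestep statistics; a long-running
  transect therefore cannot dominate its site. Within-site variability is
  the SE across a site's transects; among-site variability the SE across
  site means.
- Timestamps are naive local standard time throughout; the loggers record
  standard time year-round, so no DST handling exists anywhere.

## Community analysis

STI is the unweighted mean of a long-term temperature surface over a
species' range; the primary input is a precomputed STI table, with the
raster route provided for in-memory grids (no area weighting — at ~1-km
resolution and single-region extents the correction is negligible).
Unresolvable field codes go through substitution rules: a code may borrow a
congener's STI, or a designation covering an indistinguishable species pair
takes the mean of the two members' STIs. CTI is the stem-proportion-weighted
mean STI per plot × stratum, undefined at zero stems.

Functional groups: conifers anchor the range; broadleaves at or below the
conifer STI maximum are cold-broadleaved, above it warm-broadleaved.
Broadleaves *below the conifer minimum* are classed cold-broadleaved — the
within/above dichotomy leaves that case open, and folding it into "cold"
keeps the partition exhaustive and is the ecologically conservative choice.

Elevation regressions are per-site OLS with equal plot weights, t-based
two-sided p, 95% slope CI and a *pointwise* 95% confidence band (the band a
standard regression plot shades, not a simultaneous band). No
multiple-testing correction is applied across the suite; p-values are raw
per-regression values. A constant response returns slope 0, R² 0, p = 1
(no variation to explain, no evidence against zero). Sites with fewer than
3 plots for a response are skipped.

## Synthetic-study generator

The generator emulates a three-site, nine-transect sensor-network study:

- **Design**: 5 plots per transect, elevations strictly increasing with
  position and spanning exactly the site's relief (defaults 85 / 178 /
  312 m — shallow-basin, medium- and deep-valley topographies). Slope,
  aspect and soil covariates (depth, pH, gravimetric water content, total
  N) are drawn from plausible northeastern-forest ranges with no built-in
  elevation trend.
- **Temperatures**: T(plot, t) = base(t) + lapse(t)·Δz/100 + noise, with
  base(t) a 24-h sinusoid (amplitude 4 °C, warmest mid-afternoon) plus an
  annual sinusoid (amplitude 12 °C around a 5 °C mean, coldest
  mid-January) — the simplest periodic structure supporting hour-of-day
  summaries. lapse(t) is the ambient −0.65 °C 100 m⁻¹ except at scheduled
  timesteps, where it *is replaced by* a positive draw from a truncated
  normal; the whole transect shares one lapse per hour, so the returned
  schedule is an exact oracle for both detectors at zero noise.
- **Regimes**: inversion scheduling is Bernoulli per hour with day/night
  probabilities per regime. The default study assigns contrasting regimes
  by site — night-dominant moderate pooling (~33% of hours), day-dominant
  frequent and strong pooling (~41%), and a weak near-uniform regime
  (~22%) — so site-level seasonal frequencies span roughly 20–42% and mean
  strengths 0.8–1.6 °C 100 m⁻¹, the ranges reported for temperate
  mountain-and-basin studies of sub-canopy pooling. Day hours are 08–17
  local standard time.
- **Sensors**: each plot emits two streams with independent N(0, 0.2 °C)
  errors; the plot series is their mean, exercising the ingest averaging
  path (arithmetic mean of available sensors — unbiased under symmetric
  noise and degrading gracefully to one sensor).
- **Communities**: stem counts are multinomial over a species pool (4
  conifers, STI ~ U(1, 5); 6 broadleaves, STI ~ U(3, 10)); conifer species
  carry selection weight exp(coupling · f · (1 − r)) with f the transect's
  realized inversion fraction and r relative elevation. The default
  coupling of 8 makes conifers dominate (~90% of stems) at the bottom of a
  frequently pooling transect while the top stays near the neutral pool
  share — a composition flip of the size seen where pooling structures
  forests. Coupling 0 decouples composition from the schedule exactly.
  Overstory plots carry 60 stems, understory 40.

What the generator does **not** emulate: physical boundary-layer dynamics
(katabatic flow, radiation budgets, inversion build-up and breakup over
consecutive hours — scheduled hours are independent), snowpack and
soil-moisture feedbacks, sensor drift or burst failures, species spatial
autocorrelation beyond the elevation–frequency coupling, and differing
logging windows across sites. Passing tests therefore demonstrate that the
*statistical machinery* recovers known structure exactly or at nominal
rates; they do not validate the meteorological realism of any particular
field deployment.

## Numerical choices and problem sizes

- Per-timestep slopes: closed-form centered least squares with per-row
  missingness masks; verified against brute-force normal equations to
  1e-10. Inference-grade regressions delegate to statsmodels OLS and are
  verified against textbook formulas (t quantiles from scipy) to 1e-10.
- SEs use the n−1 sample standard deviation; n < 2 yields a missing SE
  rather than 0.
- Scheduled lapses are drawn from a normal truncated at 0 so the schedule
  invariant (positive lapse exactly when scheduled) holds for any
  mean/sd; sd = 0 gives a degenerate constant draw, used by the exactness
  tests.
- Determinism: every random quantity derives from `numpy`'s
  `default_rng` seeded via `SeedSequence([seed, stage])`; identical
  configs give byte-identical CSV output.
- Test and acceptance problem sizes are chosen for fast, stable runs on a
  single core: the default study (9 transects × ~7,000 hours) for
  frequency/strength/agreement summaries; a 4-transect, 4-month noise-free
  study for exact schedule recovery; 100 seeded replicates of a 3-transect,
  30-day study for coupling detection and 200 for null CI coverage; 200
  random instances per primitive for the brute-force oracle checks.

## Known limitations

- The raster STI route handles in-memory grids only; no geospatial file
  formats or projections (precomputed STI tables are the primary path).
- Evaluability requires only two reporting plots for the SLR method, so a
  transect temporarily reduced to its endpoints yields a two-point slope
  with no leverage diagnostics.
- Hour-of-day statistics assume at most one timestep per date-hour (an
  hourly logging grid); sub-hourly data must be aggregated first.
- The variability decomposition is descriptive (SEs at two levels), not a
  variance-components model; no significance tests compare sites.
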