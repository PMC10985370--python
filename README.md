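# coldpool

Detection and ecological analysis of **cold-air pooling** — the accumulation
of cold, dense air in valley bottoms and basins that inverts the usual
temperature–elevation relationship — from hourly sub-canopy temperature
records on elevational forest transects, together with the link from that
microclimate to forest composition.

The package is aimed at microclimate and forest ecologists who deploy paired
temperature loggers along transects (a handful of plots from a valley bottom
to an upper slope, several transects per site) and survey tree communities
in the same plots. It answers three questions: *how often* are temperature
inversions present, *how strong* are they, and *does frequent pooling leave
an inverted signature in the forest community*?

## Methods at a glance

For a transect with plots at elevations $z_1 < \dots < z_k$ and temperatures
$T_1, \dots, T_k$ at one hourly timestep:

- **Surface lapse rate (SLR)** — the least-squares slope $\beta$ of $T$ on
  $z$ (°C m⁻¹). An inversion (inverted surface lapse rate, ISLR) is present
  when $\beta > 0$; its **strength** is $100\,\beta$ (°C 100 m⁻¹).
- **Endpoint method** — an inversion is present when the last (highest)
  plot is warmer than the first (lowest): $T_\mathrm{high} > T_\mathrm{low}$,
  strictly. The **temperature difference** is
  $T_\mathrm{high} - T_\mathrm{low}$. This method stays defined when GPS
  error leaves low plots at indistinguishable elevations and is the (more
  conservative) default for reporting.
- **Frequency** — the percentage of evaluable hourly timesteps in a period
  (season, month) with an inversion present; for an hour-of-day interval,
  the percentage of dates. Site statistics are unweighted means of
  transect statistics ± 1 SE; within-site variability is the SE across a
  site's transects, among-site variability the SE across site means.
- **Community temperature index (CTI)** — per plot and stratum,
  $\mathrm{CTI} = \sum_s p_s \cdot \mathrm{STI}_s$ with $p_s$ the
  stem-count proportion of species $s$ and STI its range-wide mean
  temperature (species temperature index). Species split into conifers,
  cold-broadleaved (STI within the conifer range) and warm-broadleaved
  (above it). CTI, group abundances and soil covariates are regressed on
  elevation per site by OLS with t-based 95% CIs.

A seeded synthetic-study generator produces the whole data set — plot
network, diurnal/seasonal temperature field with a known inversion schedule,
two noisy sensor streams per plot, species pool and communities whose
conifer share increases where inversions are frequent — so every stage can
be verified against exact ground truth.

## Worked example

```python
import coldpool as cp

cfg = cp.default_study_config(seed=1)          # 3 sites x 3 transects x 5 plots
design = cp.gen_design(cfg)
temps = cp.gen_temperatures(design, cfg)       # hourly series + schedule oracle
status = cp.build_status_series(temps.plot_series, design)

freq = cp.frequency_by_period(status, cp.PeriodPartition.seasons())
site = freq[freq["scope"] == "site"]
print(site.pivot(index="site_id", columns="period", values="frequency_pct").round(1))
```

```
period   Fall 2021  Late summer 2021  Spring 2022  Winter 2021/22
site_id
S1            32.4              32.1         33.0            32.0
S2            40.8              41.7         41.7            41.3
S3            20.9              21.4         21.1            21.1
```

Each cell is the percentage of hourly timesteps in that season with an
inversion present, averaged over the site's three transects: S2 (the
day-dominant, strongly pooling site) is inverted roughly 41% of the time,
S3 (weak regime) about 21%. `cp.method_agreement(status)` on the same run
returns slope 1.00 and R² 1.00 — the two detection methods give nearly
identical monthly frequencies. The composition stage
(`analysis/04_community_cti.py`, `05_elevation_regressions.py`) then shows
overstory CTI increasing with elevation at every site (e.g. slope
0.015 °C m⁻¹, p = 0.003 at S1) with conifer proportion falling — the
inverted composition gradient that frequent cold-air pooling produces.

The numbered scripts under `analysis/` run the same pipeline as a narrative
(simulate → detect → summarise → CTI → regress), writing tables to
`results/`. The `coldpool` CLI exposes the stages
(`simulate`, `ingest`, `inversions`, `summarize`, `cti`, `regress`,
`run-all`) for shell use, and `run_pipeline` drives everything from one
YAML config.

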