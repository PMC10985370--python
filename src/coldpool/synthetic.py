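"""Seeded synthetic cold-air-pooling studies with a known inversion schedule.

The generator emulates a multi-site sensor-network study: several sites, each
with a few elevational transects of 5-6 plots, hourly sub-canopy temperature
series spanning two seasons to most of a year, and stem-count surveys of the
tree community at every plot. Temperatures follow a diurnal + annual sinusoid
plus an elevational lapse term; at scheduled timesteps the lapse flips from
the ambient (negative) rate to a positive "inverted" rate, producing a
cold-air-pool signature. The schedule of those flips is returned alongside
the data, so downstream detection and frequency statistics have an exact
ground-truth oracle.

Communities are drawn multinomially from a species pool whose conifer members
get a selection-weight boost where inversions are frequent and relative
elevation is low, reproducing (with a tunable effect size) the inverted
composition gradients cold-air pooling is hypothesised to cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ConfigError(ValueError):
    """Raised when a synthetic-study configuration is internally inconsistent."""


@dataclass(frozen=True)
class InversionRegime:
    """Hour-of-day inversion disposition for one transect.

    ``day_prob``/``night_prob`` are per-timestep probabilities that an
    inversion is scheduled during day/night hours; strength parameters are
    the mean and sd of the scheduled inverted lapse in degC per 100 m.
    """

    day_prob: float
    night_prob: float
    strength_mean: float
    strength_sd: float

    def prob_for_hours(self, hours: np.ndarray, day_hours: range) -> np.ndarray:
        is_day = np.isin(hours, list(day_hours))
        return np.where(is_day, self.day_prob, self.night_prob)


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic study.

    Defaults describe the study conditions the generator emulates: 3 sites x
    3 transects x 5 plots, hourly records from late August to early June,
    an ambient lapse of -0.65 degC 100 m^-1, inversions at roughly 30% of
    timesteps with strengths of order 1 degC 100 m^-1, and per-sensor noise
    of 0.2 degC.
    """

    seed: int
    n_sites: int = 3
    transects_per_site: int = 3
    plots_per_transect: int = 5
    elevation_spans_m: Sequence[float] = (85.0, 178.0, 312.0)  # per site, cycled
    start: str = "2021-08-21 00:00"
    end: str = "2022-06-07 23:00"
    base_lapse: float = -0.65  # degC per 100 m, negative = normal profile
    inversion_prob: float = 0.30  # per-timestep, used when regimes is None
    inversion_strength_mean: float = 1.2  # degC per 100 m, > 0
    inversion_strength_sd: float = 0.4
    regimes: Sequence[InversionRegime] | None = None
    regime_by: str = "site"  # regimes cycle over "site" or "transect"
    day_hours: range = field(default_factory=lambda: range(8, 18))
    mean_temp: float = 5.0  # degC, annual mean of the valley-bottom series
    annual_amplitude: float = 12.0
    diurnal_amplitude: float = 4.0
    noise_sd: float = 0.2  # degC, per sensor reading

    def validate(self) -> None:
        if self.n_sites < 1 or self.transects_per_site < 1:
            raise ConfigError("need at least one site and one transect per site")
        if self.plots_per_transect < 2:
            raise ConfigError(
                "plots_per_transect must be >= 2 (a transect needs endpoints)"
            )
        if not 0.0 <= self.inversion_prob <= 1.0:
            raise ConfigError("inversion_prob must lie in [0, 1]")
        if self.inversion_strength_mean <= 0:
            raise ConfigError("inversion_strength_mean must be > 0")
        if self.inversion_strength_sd < 0 or self.noise_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.regimes is not None:
            for r in self.regimes:
                if not (0 <= r.day_prob <= 1 and 0 <= r.night_prob <= 1):
                    raise ConfigError("regime probabilities must lie in [0, 1]")
                if r.strength_mean <= 0:
                    raise ConfigError("regime strength_mean must be > 0")
        if self.regime_by not in ("site", "transect"):
            raise ConfigError("regime_by must be 'site' or 'transect'")
        if len(self.time_index()) == 0:
            raise ConfigError("empty time grid: end precedes start")

    def time_index(self) -> pd.DatetimeIndex:
        """Hourly grid in naive local standard time (no DST shifts)."""
        return pd.date_range(self.start, self.end, freq="h")


def default_study_config(seed: int) -> SyntheticConfig:
    """The default nine-transect study with mixed inversion regimes.

    The three sites carry contrasting dispositions mirroring the variety seen
    in sub-canopy studies: a night-dominant site with moderate pooling
    (~33% of timesteps), a day-dominant site with frequent, strong pooling
    (as on sheltered basin floors, ~41%), and a weak near-uniform site
    (~22%) — so site-level seasonal frequencies span roughly 20-40% and
    strength means 0.8-1.6 degC 100 m^-1.
    """
    regimes = (
        InversionRegime(day_prob=0.15, night_prob=0.45, strength_mean=1.0, strength_sd=0.4),
        InversionRegime(day_prob=0.60, night_prob=0.28, strength_mean=1.6, strength_sd=0.5),
        InversionRegime(day_prob=0.18, night_prob=0.24, strength_mean=0.8, strength_sd=0.3),
    )
    return SyntheticConfig(seed=seed, regimes=regimes, regime_by="site")


def _site_ids(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def gen_design(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate the plot network: ids, transect positions, elevations, covariates.

    Within a transect, plot positions 1..k run strictly upslope; the
    elevation difference between the last and first plot equals the site's
    configured span exactly. Terrain (slope, aspect) and soil covariates
    (depth, pH, gravimetric water content, total N) are drawn from plausible
    ranges for northeastern temperate forest soils and carry no built-in
    elevation trend.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    k = cfg.plots_per_transect
    rows = []
    for si, site in enumerate(_site_ids(cfg.n_sites)):
        span = float(cfg.elevation_spans_m[si % len(cfg.elevation_spans_m)])
        for ti in range(cfg.transects_per_site):
            transect = f"{site}-T{ti + 1}"
            base_elev = rng.uniform(300.0, 420.0)
            if k > 2:
                interior = np.sort(rng.uniform(0.08, 0.92, size=k - 2))
                frac = np.concatenate([[0.0], interior, [1.0]])
            else:
                frac = np.array([0.0, 1.0])
            elevs = base_elev + span * frac
            aspect = rng.uniform(0.0, 360.0, size=k)
            for pi in range(k):
                rows.append(
                    {
                        "site_id": site,
                        "transect_id": transect,
                        "plot_id": f"{transect}-P{pi + 1}",
                        "position": pi + 1,
                        "elevation_m": elevs[pi],
                        "slope_deg": rng.uniform(2.0, 25.0),
                        "aspect_deg": aspect[pi],
                        "soil_depth_cm": float(np.clip(rng.normal(50.0, 12.0), 5.0, 90.0)),
                        "soil_ph": float(np.clip(rng.normal(4.5, 0.4), 3.0, 7.0)),
                        "soil_gwc_g_g": float(np.clip(rng.normal(0.40, 0.12), 0.05, 0.95)),
                        "soil_n_pct": float(np.clip(rng.normal(0.35, 0.10), 0.02, 1.5)),
                    }
                )
    design = pd.DataFrame(rows)
    rad = np.deg2rad(design["aspect_deg"])
    design["northness"] = np.cos(rad)
    design["eastness"] = np.sin(rad)
    return design


def _base_cycle(cfg: SyntheticConfig, times: pd.DatetimeIndex) -> np.ndarray:
    doy = times.dayofyear.to_numpy(dtype=float)
    hour = times.hour.to_numpy(dtype=float)
    annual = -cfg.annual_amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.25)
    diurnal = -cfg.diurnal_amplitude * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    return cfg.mean_temp + annual + diurnal


def _draw_lapse(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Scheduled inverted lapse: normal truncated to (0, inf); degenerate at sd=0."""
    if sd == 0.0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


@dataclass
class SyntheticTemperatures:
    """Hourly output of the temperature generator.

    ``plot_series``: plot_id, timestamp, temp_c, n_sensors (sensor-averaged).
    ``schedule``: transect_id, timestamp, inverted flag, scheduled lapse
    (degC per 100 m, NaN when not inverted) — the ground-truth oracle.
    ``sensor_readings``: two noisy sensor streams per plot, the raw input the
    ingest stage averages.
    """

    plot_series: pd.DataFrame
    schedule: pd.DataFrame
    sensor_readings: pd.DataFrame


def gen_temperatures(design: pd.DataFrame, cfg: SyntheticConfig) -> SyntheticTemperatures:
    """Generate hourly temperatures for every plot plus the inversion schedule.

    temperature(plot, t) = base(t) + lapse(t) * (elev - elev_min) / 100 + noise,
    where lapse(t) is the scheduled inverted lapse at scheduled timesteps and
    the ambient ``base_lapse`` otherwise. The whole transect shares one lapse
    per timestep, so the schedule is an exact oracle for both detection
    methods when ``noise_sd`` is zero. Each plot emits two sensor streams with
    independent N(0, noise_sd) errors; the plot series is their mean.
    """
    cfg.validate()
    times = cfg.time_index()
    if len(times) == 0:
        raise ConfigError("empty time grid")
    base = _base_cycle(cfg, times)
    hours = times.hour.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))

    tmeta = design.drop_duplicates("transect_id")
    transects = tmeta["transect_id"].tolist()
    site_index = {s: i for i, s in enumerate(tmeta["site_id"].unique())}
    sched_frames = []
    plot_frames = []
    sensor_frames = []
    nt = len(times)
    for tidx, transect in enumerate(transects):
        if cfg.regimes is not None:
            ridx = (site_index[tmeta["site_id"].iloc[tidx]]
                    if cfg.regime_by == "site" else tidx)
            regime = cfg.regimes[ridx % len(cfg.regimes)]
            prob = regime.prob_for_hours(hours, cfg.day_hours)
            s_mean, s_sd = regime.strength_mean, regime.strength_sd
        else:
            prob = np.full(nt, cfg.inversion_prob)
            s_mean, s_sd = cfg.inversion_strength_mean, cfg.inversion_strength_sd
        inverted = rng.random(nt) < prob
        lapse = np.full(nt, np.nan)
        lapse[inverted] = _draw_lapse(rng, s_mean, s_sd, int(inverted.sum()))
        applied = np.where(inverted, lapse, cfg.base_lapse)

        sub = design[design["transect_id"] == transect].sort_values("position")
        elev = sub["elevation_m"].to_numpy()
        rel = (elev - elev.min()) / 100.0
        truth = base[:, None] + applied[:, None] * rel[None, :]  # (T, P)
        e1 = rng.normal(0.0, cfg.noise_sd, size=truth.shape) if cfg.noise_sd > 0 else np.zeros_like(truth)
        e2 = rng.normal(0.0, cfg.noise_sd, size=truth.shape) if cfg.noise_sd > 0 else np.zeros_like(truth)

        sched_frames.append(
            pd.DataFrame(
                {
                    "transect_id": transect,
                    "timestamp": times,
                    "inverted": inverted,
                    "lapse_c_per_100m": lapse,
                }
            )
        )
        for j, plot in enumerate(sub["plot_id"]):
            plot_frames.append(
                pd.DataFrame(
                    {
                        "plot_id": plot,
                        "timestamp": times,
                        "temp_c": truth[:, j] + 0.5 * (e1[:, j] + e2[:, j]),
                        "n_sensors": 2,
                    }
                )
            )
            for tag, err in (("a", e1), ("b", e2)):
                sensor_frames.append(
                    pd.DataFrame(
                        {
                            "sensor_id": f"{plot}-{tag}",
                            "plot_id": plot,
                            "timestamp": times,
                            "temp_c": truth[:, j] + err[:, j],
                        }
                    )
                )

    return SyntheticTemperatures(
        plot_series=pd.concat(plot_frames, ignore_index=True),
        schedule=pd.concat(sched_frames, ignore_index=True),
        sensor_readings=pd.concat(sensor_frames, ignore_index=True),
    )


def gen_species_pool(
    n_conifer: int,
    n_broadleaf: int,
    sti_ranges: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 5.0), (3.0, 10.0)),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a species pool with temperature preferences (STI) and leaf habits.

    Conifers get STIs uniform on the first range, broadleaves on the second;
    the conifer range sits below/overlapping the broadleaf range so the
    functional-group split (conifer / cold- / warm-broadleaved) is exercised.
    Deterministic under ``seed``.
    """
    if n_conifer < 1:
        raise ConfigError("need at least one conifer (the group split requires a conifer STI range)")
    if n_broadleaf < 0:
        raise ConfigError("n_broadleaf must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    (clo, chi), (blo, bhi) = sti_ranges
    rows = []
    for i in range(n_conifer):
        rows.append({"species_code": f"CON{i + 1}", "leaf_habit": "conifer",
                     "sti_c": rng.uniform(clo, chi), "provenance": "table"})
    for i in range(n_broadleaf):
        rows.append({"species_code": f"BRD{i + 1}", "leaf_habit": "broadleaf",
                     "sti_c": rng.uniform(blo, bhi), "provenance": "table"})
    return pd.DataFrame(rows)


def gen_communities(
    design: pd.DataFrame,
    schedule: pd.DataFrame,
    pool: pd.DataFrame,
    coupling: float = 8.0,
    stems_per_plot: int = 60,
    understory_stems: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw stem-count surveys with a composition-inversion coupling.

    Per plot and stratum, counts are multinomial over the species pool.
    Conifer species carry a selection weight exp(coupling * f * (1 - r)),
    where f is the transect's realized inversion fraction (from the
    schedule) and r the plot's relative elevation within its transect
    (0 = bottom). With coupling > 0, low plots on inversion-prone transects
    are conifer-enriched — the inverted composition gradient cold-air
    pooling is hypothesised to produce; coupling = 0 decouples composition
    from the schedule entirely. The default effect size corresponds to
    conifer dominance flipping from ~90% of stems at the bottom of a
    frequently pooling transect to the pool's neutral share at the top.
    """
    if coupling < 0:
        raise ConfigError("coupling must be >= 0")
    if stems_per_plot < 1 or understory_stems < 1:
        raise ConfigError("stem counts per plot must be >= 1")
    if pool.empty:
        raise ConfigError("species pool is empty")
    missing = set(design["transect_id"]) - set(schedule["transect_id"])
    if missing:
        raise ConfigError(f"schedule covers no timesteps for transects: {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    freq = schedule.groupby("transect_id")["inverted"].mean()
    is_conifer = (pool["leaf_habit"] == "conifer").to_numpy()
    codes = pool["species_code"].to_numpy()

    rows = []
    for transect, sub in design.groupby("transect_id", sort=False):
        f = float(freq[transect])
        sub = sub.sort_values("position")
        elev = sub["elevation_m"].to_numpy()
        span = elev.max() - elev.min()
        rel = (elev - elev.min()) / span if span > 0 else np.zeros_like(elev)
        for plot, r in zip(sub["plot_id"], rel):
            w = np.ones(len(pool))
            w[is_conifer] = np.exp(coupling * f * (1.0 - r))
            p = w / w.sum()
            for stratum, stems in (("overstory", stems_per_plot), ("understory", understory_stems)):
                counts = rng.multinomial(stems, p)
                for code, c in zip(codes, counts):
                    if c > 0:
                        rows.append({"plot_id": plot, "stratum": stratum,
                                     "species_code": code, "count": int(c)})
    return pd.DataFrame(rows)


def write_study_csvs(
    out_dir: str | Path,
    design: pd.DataFrame,
    temps: SyntheticTemperatures,
    surveys: pd.DataFrame | None = None,
    pool: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a synthetic study in the CSV dialects the ingest stage reads.

    Emits plots.csv, sensors.csv, schedule.csv and, when given, surveys.csv
    and species.csv. Timestamps are ISO-8601 without zone suffix; floats keep
    full precision so a write/read round trip is lossless.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.17g")
        paths[name.removesuffix(".csv")] = p

    _write("plots.csv", design)
    _write("sensors.csv", temps.sensor_readings)
    _write("schedule.csv", temps.schedule)
    if surveys is not None:
        _write("surveys.csv", surveys)
    if pool is not None:
        _write("species.csv", pool)
    return paths
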