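"""End-to-end orchestration: data -> inversion status -> summaries -> CTI -> trends.

A run either generates a synthetic study (seeded, with its ground-truth
schedule written alongside) or ingests plot/sensor/survey CSVs, then builds
the per-timestep inversion status series, the seasonal/monthly/hourly
frequency and intensity tables, the variability decomposition, the
cross-method agreement check, plot-level CTI and functional-group
abundances, and the per-site elevation regressions. All outputs are tidy
CSVs in the output directory plus an in-memory report bundle; a run log
records the seed, configuration and row counts so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from coldpool import community, gradient, ingest, inversions, summaries, synthetic

logger = logging.getLogger("coldpool")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    out_dir: str = "coldpool_out"
    method: str = "endpoint"  # presence method for reported summaries
    use_shared_window: bool = True  # restrict hourly stats to the common window
    # synthetic route
    synthetic: synthetic.SyntheticConfig | None = None
    coupling: float = 8.0
    stems_per_plot: int = 60
    understory_stems: int = 40
    n_conifer: int = 4
    n_broadleaf: int = 6
    # file route
    plots_path: str | None = None
    sensors_path: str | None = None
    surveys_path: str | None = None
    species_path: str | None = None


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; a `synthetic:` mapping requires a seed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    cfg = PipelineConfig(**raw)
    if syn is not None:
        if "seed" not in syn:
            raise PipelineError("stage config: synthetic section must set a seed")
        regimes = syn.pop("regimes", None)
        if regimes is not None:
            syn["regimes"] = tuple(synthetic.InversionRegime(**r) for r in regimes)
        if "day_hours" in syn:
            lo, hi = syn["day_hours"]
            syn["day_hours"] = range(lo, hi)
        cfg.synthetic = synthetic.SyntheticConfig(**syn)
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(cfg: PipelineConfig):
    if cfg.synthetic is not None:
        scfg = cfg.synthetic
        design = synthetic.gen_design(scfg)
        temps = synthetic.gen_temperatures(design, scfg)
        pool = synthetic.gen_species_pool(cfg.n_conifer, cfg.n_broadleaf, seed=scfg.seed)
        surveys = synthetic.gen_communities(
            design, temps.schedule, pool,
            coupling=cfg.coupling, stems_per_plot=cfg.stems_per_plot,
            understory_stems=cfg.understory_stems, seed=scfg.seed,
        )
        return design, temps.plot_series, surveys, pool, temps.schedule
    if cfg.plots_path is None or cfg.sensors_path is None:
        raise PipelineError("stage 'inputs' failed: need either a synthetic config or plots/sensors paths")
    design = ingest.read_plots(cfg.plots_path)
    readings, qc = ingest.read_sensor_logs(cfg.sensors_path)
    logger.info("sensor QC: %d input, %d retained, %d out-of-window, %d duplicate",
                qc.n_input, qc.n_retained, qc.n_out_of_window, qc.n_duplicate)
    series = ingest.plot_hourly_series(readings, design)
    surveys = pool = None
    if cfg.surveys_path is not None and cfg.species_path is not None:
        surveys = ingest.read_surveys(cfg.surveys_path, design)
        pool = pd.read_csv(cfg.species_path)
    else:
        logger.warning("surveys/species not supplied; composition stages will be skipped")
    return design, series, surveys, pool, None


def run_pipeline(cfg: PipelineConfig | str | Path) -> dict:
    """Execute every stage and write the tidy CSV bundle.

    Returns the report bundle: a dict of DataFrames keyed by output name,
    plus ``summary`` (headline numbers as a dict). Composition stages are
    skipped with a warning when no surveys are available.
    """
    if not isinstance(cfg, PipelineConfig):
        cfg = load_config(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design, series, surveys, pool, schedule = _load_inputs(cfg)

    status = _stage("inversion_detection")(inversions.build_status_series)(
        series, design, strength_method=cfg.method
    )

    seasons, months = summaries.PeriodPartition.seasons(), summaries.PeriodPartition.months()
    hourly_status = summaries.restrict_window(status) if cfg.use_shared_window else status
    bundle: dict[str, object] = {"plots": design, "status": status}

    freq = _stage("temporal_summaries")
    bundle["frequency_by_season"] = freq(summaries.frequency_by_period)(status, seasons, cfg.method)
    bundle["frequency_by_month"] = freq(summaries.frequency_by_period)(status, months, cfg.method)
    bundle["frequency_by_hour"] = freq(summaries.hourly_frequency)(
        status, cfg.method, summaries.SHARED_WINDOW if cfg.use_shared_window else None)
    bundle["intensity_by_season"] = freq(summaries.intensity_summary)(status, seasons, cfg.method)
    bundle["intensity_by_month"] = freq(summaries.intensity_summary)(status, months, cfg.method)
    bundle["intensity_by_hour"] = freq(summaries.intensity_summary)(
        hourly_status, summaries.PeriodPartition.hours(), cfg.method)
    bundle["variability"] = freq(summaries.variability_decomposition)(
        bundle["frequency_by_season"])
    agreement = freq(summaries.method_agreement)(status)
    bundle["method_agreement"] = pd.DataFrame([agreement])

    cti = abundances = None
    if surveys is not None and pool is not None:
        comp = _stage("community_composition")
        prefs = comp(community.resolve_preferences)(surveys["species_code"], pool)
        cti = comp(community.community_temperature_index)(surveys, prefs)
        groups = comp(community.classify_functional_groups)(prefs)
        abundances = comp(community.group_abundances)(surveys, groups)
        bundle["cti_by_plot"] = cti
        bundle["group_abundance_by_plot"] = abundances
    else:
        logger.warning("no surveys: skipping CTI and functional-group stages")

    bundle["regressions"] = _stage("gradient_regressions")(gradient.elevation_trend_suite)(
        design, cti, abundances
    )
    if schedule is not None:
        bundle["schedule"] = schedule

    season_site = bundle["frequency_by_season"]
    season_site = season_site[season_site["scope"] == "site"]
    intensity_site = bundle["intensity_by_season"]
    intensity_site = intensity_site[intensity_site["scope"] == "site"]
    summary = {
        "method": cfg.method,
        "n_plots": int(len(design)),
        "n_transects": int(design["transect_id"].nunique()),
        "n_status_rows": int(len(status)),
        "seasonal_frequency_pct_min": float(season_site["frequency_pct"].min()),
        "seasonal_frequency_pct_max": float(season_site["frequency_pct"].max()),
        "mean_strength_c_per_100m_min": float(intensity_site["mean_strength"].min()),
        "mean_strength_c_per_100m_max": float(intensity_site["mean_strength"].max()),
        "method_agreement_slope": agreement["slope"],
        "method_agreement_r2": agreement["r2"],
    }
    bundle["summary"] = summary

    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    log = {"config": _config_dict(cfg), "summary": summary}
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline complete: %d outputs in %s", len(bundle), out)
    return bundle


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if cfg.synthetic is not None:
        d["synthetic"]["day_hours"] = [cfg.synthetic.day_hours.start, cfg.synthetic.day_hours.stop]
        d["synthetic"]["regimes"] = (
            [asdict(r) for r in cfg.synthetic.regimes] if cfg.synthetic.regimes else None
        )
    return d
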