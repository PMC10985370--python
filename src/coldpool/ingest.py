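"""Read, validate and normalise plot, sensor-log and survey tables.

All inputs are comma-separated UTF-8 CSV with a header row and "." decimals;
timestamps are ISO-8601 in naive local standard time (the loggers record
local standard time year-round, so there are no DST transitions to resolve).
Sensor plausibility filtering and deduplication are tracked in a QC report so
dropped + retained row counts always reconcile with the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


PLOT_REQUIRED = ["site_id", "transect_id", "plot_id", "position", "elevation_m"]
SENSOR_REQUIRED = ["sensor_id", "plot_id", "timestamp", "temp_c"]
SURVEY_REQUIRED = ["plot_id", "stratum", "species_code", "count"]
STRATA = ("overstory", "understory")

#: Default plausibility window for hourly air temperature, degC.
TEMP_WINDOW = (-45.0, 45.0)


@dataclass
class QCReport:
    """Row-level accounting for one ingest pass."""

    n_input: int = 0
    n_retained: int = 0
    n_out_of_window: int = 0
    n_unparseable: int = 0
    n_duplicate: int = 0
    dropped_rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped_rows,
                            columns=["reason", "sensor_id", "timestamp", "temp_c"])


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing required columns {missing}")


def read_plots(path: str | Path) -> pd.DataFrame:
    """Read and validate the plot metadata table.

    Computes northness = cos(aspect) and eastness = sin(aspect) (aspect in
    radians) when absent, so northness runs from 1 at 0 deg (north) to -1 at
    180 deg (south) and eastness from 1 at 90 deg (east) to -1 at 270 deg.
    """
    df = pd.read_csv(path)
    _require_columns(df, PLOT_REQUIRED, "plots")
    if not np.issubdtype(df["elevation_m"].dtype, np.number):
        raise ValidationError("plots: elevation_m must be numeric")
    if df["elevation_m"].isna().any() or not np.isfinite(df["elevation_m"]).all():
        raise ValidationError("plots: elevation_m contains missing/non-finite values")
    dup = df.duplicated(subset=["transect_id", "position"])
    if dup.any():
        bad = df.loc[dup, ["transect_id", "position"]].to_dict("records")
        raise ValidationError(f"plots: duplicate (transect, position) pairs: {bad}")
    if df["plot_id"].duplicated().any():
        raise ValidationError("plots: duplicate plot_id")
    if "aspect_deg" in df.columns:
        rad = np.deg2rad(df["aspect_deg"])
        if "northness" not in df.columns:
            df["northness"] = np.cos(rad)
        if "eastness" not in df.columns:
            df["eastness"] = np.sin(rad)
    return df


def read_sensor_logs(
    paths: str | Path | Iterable[str | Path],
    window: tuple[float, float] = TEMP_WINDOW,
) -> tuple[pd.DataFrame, QCReport]:
    """Read sensor logs, apply the plausibility window, deduplicate.

    Returns the retained readings and a :class:`QCReport`. Out-of-window
    temperatures and unparseable timestamps are dropped (and logged);
    duplicate (sensor_id, timestamp) rows collapse to their first occurrence.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"sensor log not found: {p}")
        frames.append(pd.read_csv(p))
    df = pd.concat(frames, ignore_index=True)
    _require_columns(df, SENSOR_REQUIRED, "sensors")

    qc = QCReport(n_input=len(df))
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad_ts = ts.isna()
    for _, row in df[bad_ts].iterrows():
        qc.dropped_rows.append({"reason": "unparseable_timestamp", "sensor_id": row["sensor_id"],
                                "timestamp": row["timestamp"], "temp_c": row["temp_c"]})
    qc.n_unparseable = int(bad_ts.sum())
    df = df[~bad_ts].copy()
    df["timestamp"] = ts[~bad_ts]

    temp = pd.to_numeric(df["temp_c"], errors="coerce")
    lo, hi = window
    out = temp.isna() | (temp < lo) | (temp > hi)
    if out.any():
        for _, row in df[out].head(1000).iterrows():
            qc.dropped_rows.append({"reason": "out_of_window", "sensor_id": row["sensor_id"],
                                    "timestamp": row["timestamp"], "temp_c": row["temp_c"]})
    qc.n_out_of_window = int(out.sum())
    df = df[~out].copy()
    df["temp_c"] = temp[~out]

    before = len(df)
    df = df.drop_duplicates(subset=["sensor_id", "timestamp"], keep="first")
    qc.n_duplicate = before - len(df)
    qc.n_retained = len(df)
    return df.reset_index(drop=True), qc


def plot_hourly_series(
    readings: pd.DataFrame, plots: pd.DataFrame
) -> pd.DataFrame:
    """Combine sensors into a QC'd plot-level hourly series.

    The plot temperature at a timestep is the arithmetic mean of whichever of
    the plot's sensors reported (the sensors are interchangeable replicates
    hung within the same plot); ``n_sensors`` records how many contributed.
    Each transect's plots are aligned on the union of their observed hourly
    grids, so timesteps where a plot is silent appear with ``n_sensors`` = 0
    and a missing temperature. Plots with no readings at all are excluded.
    """
    known = set(plots["plot_id"])
    unknown = set(readings["plot_id"]) - known
    if unknown:
        raise ValidationError(f"sensor readings reference unknown plots: {sorted(unknown)}")

    agg = (
        readings.groupby(["plot_id", "timestamp"])["temp_c"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "temp_c", "size": "n_sensors"})
        .reset_index()
    )
    meta = plots.set_index("plot_id")["transect_id"]
    agg["transect_id"] = agg["plot_id"].map(meta)

    frames = []
    for transect, sub in agg.groupby("transect_id", sort=False):
        grid = pd.DatetimeIndex(sorted(sub["timestamp"].unique()))
        for plot, psub in sub.groupby("plot_id", sort=False):
            s = psub.set_index("timestamp").reindex(grid)
            frames.append(pd.DataFrame({
                "plot_id": plot,
                "timestamp": grid,
                "temp_c": s["temp_c"].to_numpy(),
                "n_sensors": s["n_sensors"].fillna(0).astype(int).to_numpy(),
            }))
    if not frames:
        return pd.DataFrame(columns=["plot_id", "timestamp", "temp_c", "n_sensors"])
    return pd.concat(frames, ignore_index=True)


def read_surveys(path: str | Path, plots: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate stem-count surveys.

    Species codes are normalised (upper case, stripped); strata must be
    'overstory' or 'understory'; counts must be non-negative integers and
    (plot, stratum, species) unique. When ``plots`` is given, survey plot ids
    must be known.
    """
    df = pd.read_csv(path)
    _require_columns(df, SURVEY_REQUIRED, "surveys")
    df = df.copy()
    df["species_code"] = df["species_code"].astype(str).str.strip().str.upper()
    df["stratum"] = df["stratum"].astype(str).str.strip().str.lower()
    bad_stratum = ~df["stratum"].isin(STRATA)
    if bad_stratum.any():
        seen = sorted(df.loc[bad_stratum, "stratum"].unique())
        raise ValidationError(f"surveys: unknown strata {seen}; allowed: {list(STRATA)}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any() or (counts < 0).any() or (counts % 1 != 0).any():
        raise ValidationError("surveys: counts must be non-negative integers")
    df["count"] = counts.astype(int)
    if df.duplicated(subset=["plot_id", "stratum", "species_code"]).any():
        raise ValidationError("surveys: duplicate (plot, stratum, species) rows")
    if plots is not None:
        unknown = set(df["plot_id"]) - set(plots["plot_id"])
        if unknown:
            raise ValidationError(f"surveys: unknown plot ids {sorted(unknown)}")
    return df
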