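"""Per-timestep temperature-inversion detection on elevational transects.

A transect at an hourly timestep carries one temperature per plot. Two
standard detection methods are computed side by side:

* **SLR method** — the surface lapse rate (SLR) is the least-squares slope of
  temperature on elevation across the transect's plots; an inversion (an
  inverted surface lapse rate, ISLR) is present when the slope is strictly
  positive. Strength is the slope re-expressed in degC per 100 m.
* **Endpoint method** — compare the plots positioned first (low elevation)
  and last (high elevation) along the transect: an inversion is present when
  T_high > T_low, strictly. The signed difference T_high - T_low is reported
  as the temperature difference whether or not an inversion is present.

Both use strict inequalities, so a perfectly flat profile counts as no
inversion. Endpoints are defined by transect *position*, not by elevation
rank — the endpoint method stays well defined even when GPS error leaves two
low plots at indistinguishable elevations, which is exactly the situation
that motivates carrying it alongside the regression method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUS_COLUMNS = [
    "site_id", "transect_id", "timestamp", "n_plots",
    "slr_c_per_m", "islr_evaluable", "islr_present",
    "endpoint_evaluable", "endpoint_present",
    "temp_diff_c", "strength_c_per_100m",
]


def surface_lapse_rate(elevations: np.ndarray, temperatures: np.ndarray) -> float:
    """Least-squares slope of temperature (degC) on elevation (m).

    Plots with missing temperature are ignored. Returns NaN when fewer than
    two observations remain or all remaining elevations coincide (the slope
    is then undefined and the SLR method is not evaluable). With exactly two
    points this degenerates to the two-point slope.
    """
    x = np.asarray(elevations, dtype=float)
    y = np.asarray(temperatures, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        return np.nan
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        return np.nan
    return float(xc @ (y - y.mean())) / sxx


def detect_endpoint(t_low: float, t_high: float) -> tuple[bool, float]:
    """Endpoint comparison: present iff T_high > T_low (strict).

    Returns (flag, temp_diff) with temp_diff = T_high - T_low; with either
    endpoint missing the timestep is not evaluable and (False, NaN) is
    returned — callers must exclude such timesteps from denominators.
    """
    diff = t_high - t_low
    if np.isnan(diff):
        return False, np.nan
    return bool(diff > 0.0), float(diff)


def _transect_status(
    temps: np.ndarray, elev: np.ndarray, first: int, last: int
) -> dict[str, np.ndarray]:
    """Vectorised per-timestep status for one transect.

    ``temps`` is (T, P) with NaN for missing; columns ordered by position.
    The closed-form OLS slope is evaluated row-wise with per-row masking, so
    a plot that drops out for part of the record simply leaves the
    regression for those hours.
    """
    mask = ~np.isnan(temps)
    n = mask.sum(axis=1).astype(float)
    x = np.where(mask, elev[None, :], 0.0)
    y = np.where(mask, temps, 0.0)
    sx, sy = x.sum(axis=1), y.sum(axis=1)
    sxx, sxy = (x * x).sum(axis=1), (x * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = sxx - sx * sx / np.where(n > 0, n, np.nan)
        slr = (sxy - sx * sy / np.where(n > 0, n, np.nan)) / denom
    islr_eval = (n >= 2) & np.isfinite(slr)
    slr = np.where(islr_eval, slr, np.nan)

    t_low, t_high = temps[:, first], temps[:, last]
    diff = t_high - t_low
    ep_eval = ~np.isnan(diff)
    return {
        "n_plots": mask.sum(axis=1),
        "slr_c_per_m": slr,
        "islr_evaluable": islr_eval,
        "islr_present": islr_eval & (slr > 0.0),
        "endpoint_evaluable": ep_eval,
        "endpoint_present": ep_eval & (diff > 0.0),
        "temp_diff_c": diff,
    }


def build_status_series(
    plot_series: pd.DataFrame,
    plots: pd.DataFrame,
    strength_method: str = "endpoint",
) -> pd.DataFrame:
    """Evaluate both detection methods for every transect x hourly timestep.

    ``strength_method`` selects which method's presence flag conditions the
    reported inversion strength (100 x SLR, degC per 100 m): ``"endpoint"``
    (default, the more conservative flag) or ``"islr"``. At an
    endpoint-flagged timestep with a non-monotone profile the regression
    slope can be non-positive; the slope value is still recorded as strength
    so the strength series faithfully reflects the fitted gradient.

    Returns one row per transect x timestep with columns
    :data:`STATUS_COLUMNS`; timesteps where neither method is evaluable are
    retained with both evaluable flags False so denominators stay auditable.
    """
    if strength_method not in ("endpoint", "islr"):
        raise ValueError("strength_method must be 'endpoint' or 'islr'")
    meta = plots.sort_values(["transect_id", "position"])
    site_of = meta.drop_duplicates("transect_id").set_index("transect_id")["site_id"]

    wide = plot_series.pivot(index="timestamp", columns="plot_id", values="temp_c")
    frames = []
    for transect, sub in meta.groupby("transect_id", sort=False):
        cols = [p for p in sub["plot_id"] if p in wide.columns]
        if len(cols) < 2:
            continue  # transect unusable: fewer than two plots ever reported
        sub = sub[sub["plot_id"].isin(cols)]
        block = wide[cols]
        block = block.dropna(how="all")
        temps = block.to_numpy(dtype=float)
        elev = sub["elevation_m"].to_numpy(dtype=float)
        status = _transect_status(temps, elev, first=0, last=len(cols) - 1)
        df = pd.DataFrame(status)
        df.insert(0, "timestamp", block.index.to_numpy())
        df.insert(0, "transect_id", transect)
        df.insert(0, "site_id", site_of[transect])
        flag = df["endpoint_present"] if strength_method == "endpoint" else df["islr_present"]
        df["strength_c_per_100m"] = np.where(flag, 100.0 * df["slr_c_per_m"], np.nan)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=STATUS_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[STATUS_COLUMNS]
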