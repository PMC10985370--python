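"""Frequency, intensity and variability summaries of inversion status.

Inversion frequency for a period is the percentage of *evaluable* hourly
timesteps at which an inversion was present; for an hour-of-day interval it
is the percentage of dates whose timestep at that hour was inverted. Site
level statistics are always unweighted means of the site's transect-level
statistics (+/- 1 SE across transects), never pooled-timestep statistics, so
a transect with a longer record does not dominate its site.

Built-in period partitions follow the study calendar: four seasons
(late summer 2021 through spring 2022), calendar months, and the 24
hour-of-day intervals, with an optional shared fall-winter window for
cross-transect comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

#: Season name -> inclusive (start_date, end_date). The printed ranges abut,
#: and boundary days are taken inclusively on both ends.
SEASON_RANGES: dict[str, tuple[str, str]] = {
    "Late summer 2021": ("2021-08-21", "2021-09-24"),
    "Fall 2021": ("2021-09-25", "2021-12-21"),
    "Winter 2021/22": ("2021-12-22", "2022-03-12"),
    "Spring 2022": ("2022-03-13", "2022-06-07"),
}

#: Widest window shared by all transects (fall + winter), used for
#: hour-of-day comparisons.
SHARED_WINDOW: tuple[str, str] = ("2021-09-25", "2022-03-12")


@dataclass(frozen=True)
class PeriodPartition:
    """A named, non-overlapping assignment of timestamps to periods."""

    name: str
    assign: Callable[[pd.Series], pd.Series]

    @staticmethod
    def seasons(ranges: dict[str, tuple[str, str]] | None = None) -> "PeriodPartition":
        ranges = dict(SEASON_RANGES if ranges is None else ranges)
        bounds = {
            label: (pd.Timestamp(a), pd.Timestamp(b) + pd.Timedelta(days=1))
            for label, (a, b) in ranges.items()
        }

        def _assign(ts: pd.Series) -> pd.Series:
            out = pd.Series(pd.NA, index=ts.index, dtype=object)
            for label, (a, b) in bounds.items():
                out[(ts >= a) & (ts < b)] = label
            return out

        return PeriodPartition("season", _assign)

    @staticmethod
    def months() -> "PeriodPartition":
        return PeriodPartition(
            "month", lambda ts: ts.dt.strftime("%Y-%m").astype(object)
        )

    @staticmethod
    def hours() -> "PeriodPartition":
        return PeriodPartition("hour", lambda ts: ts.dt.hour.astype(object))


def restrict_window(status: pd.DataFrame, window: tuple[str, str] = SHARED_WINDOW) -> pd.DataFrame:
    """Keep timesteps within an inclusive [start_date, end_date] window."""
    a = pd.Timestamp(window[0])
    b = pd.Timestamp(window[1]) + pd.Timedelta(days=1)
    ts = status["timestamp"]
    return status[(ts >= a) & (ts < b)]


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return np.nan
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def _method_cols(method: str) -> tuple[str, str]:
    if method not in ("endpoint", "islr"):
        raise ValueError("method must be 'endpoint' or 'islr'")
    return f"{method}_present", f"{method}_evaluable"


def _site_rollup(transect_df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Site-level rows: per period, unweighted mean +/- SE of transect values."""
    rows = []
    for (site, period), sub in transect_df.groupby(["site_id", "period"], sort=False):
        row = {"scope": "site", "site_id": site, "transect_id": pd.NA,
               "period": period, "n_transects": len(sub)}
        for col in value_cols:
            vals = sub[col].to_numpy(dtype=float)
            row[col] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
            row[f"{col}_se"] = _sem(vals)
        rows.append(row)
    return pd.DataFrame(rows)


def frequency_by_period(
    status: pd.DataFrame,
    partition: PeriodPartition,
    method: str = "endpoint",
) -> pd.DataFrame:
    """Inversion frequency per transect x period, with site-level rollups.

    frequency_pct = 100 * (inversion timesteps / evaluable timesteps) within
    the period. Periods with no evaluable timestep for a transect are absent
    from the output (frequency is undefined there, never zero).
    """
    present_col, eval_col = _method_cols(method)
    df = status[status[eval_col]].copy()
    df["period"] = partition.assign(df["timestamp"])
    df = df[df["period"].notna()]
    grouped = (
        df.groupby(["site_id", "transect_id", "period"], sort=False)
        .agg(n_inversions=(present_col, "sum"), n_evaluable=(present_col, "size"))
        .reset_index()
    )
    grouped["frequency_pct"] = 100.0 * grouped["n_inversions"] / grouped["n_evaluable"]
    grouped.insert(0, "scope", "transect")
    site = _site_rollup(grouped, ["frequency_pct"])
    return pd.concat([grouped, site], ignore_index=True)


def hourly_frequency(
    status: pd.DataFrame,
    method: str = "endpoint",
    window: tuple[str, str] | None = SHARED_WINDOW,
) -> pd.DataFrame:
    """Percentage of dates with an inversion at each hour-of-day interval.

    Numerator: dates whose timestep at that hour is an inversion; denominator:
    dates with an evaluable timestep at that hour. Restricted by default to
    the shared fall-winter window so transects are compared over identical
    dates. Hours with no evaluable date for a transect are absent.
    """
    present_col, eval_col = _method_cols(method)
    df = restrict_window(status, window) if window is not None else status
    df = df[df[eval_col]].copy()
    df["hour"] = df["timestamp"].dt.hour
    df["date"] = df["timestamp"].dt.normalize()
    daily = (
        df.groupby(["site_id", "transect_id", "hour", "date"], sort=False)[present_col]
        .any()
        .reset_index()
    )
    grouped = (
        daily.groupby(["site_id", "transect_id", "hour"], sort=False)
        .agg(n_inversion_dates=(present_col, "sum"), n_dates=(present_col, "size"))
        .reset_index()
    )
    grouped["frequency_pct"] = 100.0 * grouped["n_inversion_dates"] / grouped["n_dates"]
    grouped = grouped.rename(columns={"hour": "period"})
    grouped.insert(0, "scope", "transect")
    site = _site_rollup(grouped, ["frequency_pct"])
    return pd.concat([grouped, site], ignore_index=True)


def intensity_summary(
    status: pd.DataFrame,
    partition: PeriodPartition,
    method: str = "endpoint",
) -> pd.DataFrame:
    """Mean strength and temperature difference over inversion timesteps.

    Per transect x period: arithmetic mean and SE of inversion strength
    (degC per 100 m) and of the endpoint temperature difference (degC), plus
    the maximum temperature difference, over the timesteps the chosen method
    flags as inversions. Site rows hold the mean of transect means (+/- SE
    across transects) and the site-wide maximum.
    """
    present_col, _ = _method_cols(method)
    df = status[status[present_col]].copy()
    df["period"] = partition.assign(df["timestamp"])
    df = df[df["period"].notna()]
    rows = []
    for (site, transect, period), sub in df.groupby(
        ["site_id", "transect_id", "period"], sort=False
    ):
        # strength re-derived from the fitted slope at the flagged timesteps,
        # so the summary honours whichever method conditions this call
        strength = 100.0 * sub["slr_c_per_m"].to_numpy(dtype=float)
        diff = sub["temp_diff_c"].to_numpy(dtype=float)
        rows.append({
            "scope": "transect", "site_id": site, "transect_id": transect,
            "period": period, "n_inversions": len(sub),
            "mean_strength": np.nanmean(strength) if np.isfinite(strength).any() else np.nan,
            "mean_strength_se": _sem(strength),
            "mean_temp_diff": np.nanmean(diff) if np.isfinite(diff).any() else np.nan,
            "mean_temp_diff_se": _sem(diff),
            "max_temp_diff": np.nanmax(diff) if np.isfinite(diff).any() else np.nan,
        })
    transect_df = pd.DataFrame(rows)
    if transect_df.empty:
        return transect_df
    site = _site_rollup(transect_df, ["mean_strength", "mean_temp_diff"])
    if not site.empty:
        site_max = (
            transect_df.groupby(["site_id", "period"], sort=False)["max_temp_diff"]
            .max()
            .reset_index()
        )
        site = site.merge(site_max, on=["site_id", "period"], how="left")
    return pd.concat([transect_df, site], ignore_index=True)


def variability_decomposition(
    transect_values: pd.DataFrame,
    value_col: str = "frequency_pct",
) -> pd.DataFrame:
    """Within- vs among-site variability of a transect-level statistic.

    Within-site variability is the SE of the statistic across a site's
    transects (per site and period); among-site variability is the SE across
    the site means (per period). Sample sd uses the n-1 denominator; levels
    with fewer than two members report a missing SE.
    """
    df = transect_values[transect_values["scope"] == "transect"] if "scope" in transect_values else transect_values
    rows = []
    for (site, period), sub in df.groupby(["site_id", "period"], sort=False):
        rows.append({"level": "within_site", "site_id": site, "period": period,
                     "se": _sem(sub[value_col].to_numpy()), "n": len(sub)})
    site_means = (
        df.groupby(["site_id", "period"], sort=False)[value_col].mean().reset_index()
    )
    for period, sub in site_means.groupby("period", sort=False):
        rows.append({"level": "among_site", "site_id": pd.NA, "period": period,
                     "se": _sem(sub[value_col].to_numpy()), "n": len(sub)})
    return pd.DataFrame(rows)


def method_agreement(status: pd.DataFrame) -> dict[str, float]:
    """Cross-method check: regress monthly endpoint frequencies on SLR-method ones.

    Computes monthly inversion frequencies per transect under both detection
    methods and fits a least-squares line (endpoint on SLR-method). Strong
    agreement shows up as slope and R^2 near 1. Returns slope ``m``,
    ``r2``, ``intercept`` and the number of paired (transect, month) points;
    with fewer than 3 pairs or a constant predictor the fit is undefined and
    NaNs are returned.
    """
    months = PeriodPartition.months()
    paired = None
    for method in ("islr", "endpoint"):
        f = frequency_by_period(status, months, method=method)
        f = f[f["scope"] == "transect"][["transect_id", "period", "frequency_pct"]]
        f = f.rename(columns={"frequency_pct": method})
        paired = f if paired is None else paired.merge(f, on=["transect_id", "period"])
    paired = paired.dropna(subset=["islr", "endpoint"])
    n = len(paired)
    if n < 3 or np.ptp(paired["islr"].to_numpy()) == 0.0:
        return {"slope": np.nan, "r2": np.nan, "intercept": np.nan, "n": n}
    fit = stats.linregress(paired["islr"], paired["endpoint"])
    return {"slope": float(fit.slope), "r2": float(fit.rvalue**2),
            "intercept": float(fit.intercept), "n": n}
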