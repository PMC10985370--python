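"""Elevation-gradient regressions with 95% confidence intervals.

Each response (CTI per stratum, functional-group abundance, soil covariates)
is regressed on plot elevation by ordinary least squares, separately per
site. Inference uses the t distribution with n-2 degrees of freedom:
two-sided p for slope = 0, a 95% CI for the slope, and a pointwise 95%
confidence band for the mean response over the observed elevation range (the
band a standard regression plot shades). Plots are weighted equally. No
multiple-testing correction is applied across the suite; p-values are raw
per-regression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RegressionResult:
    """OLS fit of one response against elevation."""

    response: str
    site_id: str | None
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_ci: tuple[float, float]
    band_x: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray

    def to_row(self) -> dict:
        return {
            "response": self.response, "site_id": self.site_id, "n": self.n,
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "slope_ci_low": self.slope_ci[0], "slope_ci_high": self.slope_ci[1],
        }


def ols_with_ci(
    x: np.ndarray,
    y: np.ndarray,
    response: str = "y",
    site_id: str | None = None,
    alpha: float = 0.05,
    n_band: int = 50,
) -> RegressionResult:
    """OLS of y on x with t-based slope CI and pointwise confidence band.

    Requires n >= 3 and non-constant x for inference; with a perfect fit the
    residual variance is zero and the CI collapses onto the estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 observations for inference, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor is constant; slope undefined")

    grid = np.linspace(x.min(), x.max(), n_band)
    if np.ptp(y) == 0.0:
        # constant response: zero slope with zero residual variance; there is
        # no variation to explain, so R^2 = 0 and the slope test carries no
        # evidence against zero
        return RegressionResult(
            response=response, site_id=site_id, n=n,
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            slope_ci=(0.0, 0.0), band_x=grid,
            band_lower=np.full(n_band, y[0]), band_upper=np.full(n_band, y[0]),
        )
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)
    pred = fit.get_prediction(sm.add_constant(grid)).conf_int(alpha=alpha)
    return RegressionResult(
        response=response,
        site_id=site_id,
        n=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        band_x=grid,
        band_lower=pred[:, 0],
        band_upper=pred[:, 1],
    )


#: Soil covariate columns picked up from the plot table when present.
SOIL_RESPONSES = ["soil_depth_cm", "soil_ph", "soil_gwc_g_g", "soil_n_pct"]


def elevation_trend_suite(
    plots: pd.DataFrame,
    cti: pd.DataFrame | None = None,
    abundances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit every response against elevation, per site; return a tidy table.

    Responses: CTI per stratum, each functional group's stem proportion per
    stratum, and any soil covariates found in the plot table. Sites with
    fewer than 3 plots carrying a response are skipped for that response.
    """
    elev = plots.set_index("plot_id")["elevation_m"]
    site_of = plots.set_index("plot_id")["site_id"]

    tasks: list[tuple[str, pd.DataFrame]] = []
    if cti is not None and not cti.empty:
        for stratum, sub in cti.groupby("stratum", sort=False):
            tasks.append((f"cti_{stratum}", sub.set_index("plot_id")[["cti_c"]]
                          .rename(columns={"cti_c": "value"})))
    if abundances is not None and not abundances.empty:
        for (stratum, grp), sub in abundances.groupby(["stratum", "functional_group"], sort=False):
            tasks.append((f"{grp}_proportion_{stratum}",
                          sub.set_index("plot_id")[["proportion"]]
                          .rename(columns={"proportion": "value"})))
    for col in SOIL_RESPONSES:
        if col in plots.columns:
            tasks.append((col, plots.set_index("plot_id")[[col]]
                          .rename(columns={col: "value"})))

    rows = []
    for response, values in tasks:
        df = values.copy()
        df["elevation_m"] = elev.reindex(df.index)
        df["site_id"] = site_of.reindex(df.index)
        df = df.dropna(subset=["value", "elevation_m", "site_id"])
        for site, sub in df.groupby("site_id", sort=False):
            if len(sub) < 3 or np.ptp(sub["elevation_m"].to_numpy()) == 0.0:
                continue
            res = ols_with_ci(sub["elevation_m"].to_numpy(), sub["value"].to_numpy(),
                              response=response, site_id=site)
            rows.append(res.to_row())
    return pd.DataFrame(rows)
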