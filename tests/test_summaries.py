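"""Frequency/intensity aggregation, variability decomposition, method agreement."""

import numpy as np
import pandas as pd
import pytest

from coldpool import summaries
from coldpool.inversions import build_status_series
from coldpool.summaries import (
    PeriodPartition,
    frequency_by_period,
    hourly_frequency,
    intensity_summary,
    method_agreement,
    variability_decomposition,
)
from coldpool.synthetic import gen_design, gen_temperatures


def _make_status(present, timestamps, transect="T1", site="S1", evaluable=None,
                 slr=None, diff=None):
    n = len(timestamps)
    present = np.asarray(present, bool)
    return pd.DataFrame({
        "site_id": site, "transect_id": transect,
        "timestamp": pd.DatetimeIndex(timestamps),
        "n_plots": 4,
        "slr_c_per_m": np.full(n, 0.01) if slr is None else np.asarray(slr, float),
        "islr_evaluable": True if evaluable is None else evaluable,
        "islr_present": present,
        "endpoint_evaluable": True if evaluable is None else evaluable,
        "endpoint_present": present,
        "temp_diff_c": np.where(present, 1.0, -1.0) if diff is None else np.asarray(diff, float),
        "strength_c_per_100m": np.where(present, 1.0, np.nan),
    })


class TestFrequency:
    def test_proportion_of_evaluable_timesteps(self):
        times = pd.date_range("2021-10-01", periods=100, freq="h")
        status = _make_status([True] * 25 + [False] * 75, times)
        out = frequency_by_period(status, PeriodPartition.months())
        row = out[out["scope"] == "transect"].iloc[0]
        assert row["frequency_pct"] == 25.0
        assert row["n_inversions"] == 25 and row["n_evaluable"] == 100

    @pytest.mark.parametrize("flags,expected", [([False] * 500, 0.0), ([True] * 500, 100.0)])
    def test_bounds(self, flags, expected):
        times = pd.date_range("2021-10-01", periods=500, freq="h")
        out = frequency_by_period(_make_status(flags, times), PeriodPartition.months())
        assert (out[out["scope"] == "transect"]["frequency_pct"] == expected).all()

    def test_non_evaluable_timesteps_excluded_from_denominator(self):
        times = pd.date_range("2021-10-01", periods=10, freq="h")
        evaluable = np.array([True] * 5 + [False] * 5)
        status = _make_status([True] * 2 + [False] * 8, times, evaluable=evaluable)
        out = frequency_by_period(status, PeriodPartition.months())
        assert out[out["scope"] == "transect"].iloc[0]["n_evaluable"] == 5

    def test_empty_period_is_missing_not_zero(self):
        times = pd.date_range("2021-10-01", periods=24, freq="h")
        status = _make_status([True] * 24, times, evaluable=np.zeros(24, bool))
        out = frequency_by_period(status, PeriodPartition.months())
        assert out.empty

    def test_site_level_is_unweighted_mean_of_transects(self):
        # transects of very different record lengths: the site value must be
        # the mean of per-transect frequencies, not the pooled proportion
        t_a = pd.date_range("2021-10-01", periods=600, freq="h")  # within one month
        t_b = pd.date_range("2021-10-01", periods=100, freq="h")
        status = pd.concat([
            _make_status([True] * 600, t_a, transect="A"),
            _make_status([False] * 100, t_b, transect="B"),
        ], ignore_index=True)
        out = frequency_by_period(status, PeriodPartition.months())
        site = out[out["scope"] == "site"]
        assert np.allclose(site["frequency_pct"], 50.0)  # (100 + 0) / 2

    def test_monthly_numerators_sum_to_season_numerator(self, tiny_study):
        design, temps = tiny_study
        status = build_status_series(temps.plot_series, design)
        months = frequency_by_period(status, PeriodPartition.months())
        seasons = frequency_by_period(status, PeriodPartition.seasons())
        m = months[months["scope"] == "transect"]
        s = seasons[seasons["scope"] == "transect"]
        # the tiny study sits wholly inside one season (fall 2021)
        assert set(s["period"]) == {"Fall 2021"}
        total = m.groupby("transect_id")["n_inversions"].sum()
        for _, row in s.iterrows():
            assert row["n_inversions"] == total[row["transect_id"]]


class TestHourlyFrequency:
    def test_percentage_of_dates(self):
        days = pd.date_range("2021-10-01", periods=60, freq="D")
        times = days + pd.Timedelta(hours=2)
        flags = [True] * 30 + [False] * 30
        out = hourly_frequency(_make_status(flags, times), window=None)
        row = out[out["scope"] == "transect"].iloc[0]
        assert row["period"] == 2 and row["frequency_pct"] == 50.0

    def test_always_inverted_hour_is_100(self):
        days = pd.date_range("2021-10-01", periods=10, freq="D")
        out = hourly_frequency(_make_status([True] * 10, days + pd.Timedelta(hours=5)),
                               window=None)
        assert (out[out["scope"] == "transect"]["frequency_pct"] == 100.0).all()

    def test_shared_window_restriction(self):
        inside = pd.date_range("2021-10-01", periods=5, freq="D") + pd.Timedelta(hours=3)
        outside = pd.date_range("2022-05-01", periods=20, freq="D") + pd.Timedelta(hours=3)
        status = _make_status([True] * 5 + [False] * 20, inside.append(outside))
        out = hourly_frequency(status, window=summaries.SHARED_WINDOW)
        row = out[out["scope"] == "transect"].iloc[0]
        assert row["n_dates"] == 5 and row["frequency_pct"] == 100.0


class TestIntensity:
    def test_mean_and_se_of_strength(self):
        times = pd.date_range("2021-10-01", periods=3, freq="h")
        status = _make_status([True] * 3, times, slr=[0.01, 0.02, 0.03])
        out = intensity_summary(status, PeriodPartition.months())
        row = out[out["scope"] == "transect"].iloc[0]
        assert row["mean_strength"] == pytest.approx(2.0)
        assert row["mean_strength_se"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-3)

    def test_single_inversion_has_no_se(self):
        times = pd.date_range("2021-10-01", periods=1, freq="h")
        status = _make_status([True], times, slr=[0.024])
        row = intensity_summary(status, PeriodPartition.months()).iloc[0]
        assert row["mean_strength"] == pytest.approx(2.4)
        assert np.isnan(row["mean_strength_se"])

    def test_max_temp_diff(self):
        times = pd.date_range("2021-10-01", periods=2, freq="h")
        status = _make_status([True, True], times, diff=[0.5, 16.2])
        row = intensity_summary(status, PeriodPartition.months()).iloc[0]
        assert row["max_temp_diff"] == 16.2
        assert row["max_temp_diff"] >= row["mean_temp_diff"]

    def test_no_inversions_yields_empty_summary(self):
        times = pd.date_range("2021-10-01", periods=10, freq="h")
        out = intensity_summary(_make_status([False] * 10, times), PeriodPartition.months())
        assert out.empty


class TestVariability:
    def test_within_site_se(self):
        df = pd.DataFrame({"site_id": "S1", "transect_id": ["A", "B", "C"],
                           "period": "Fall 2021", "frequency_pct": [10.0, 20.0, 30.0]})
        out = variability_decomposition(df)
        within = out[out["level"] == "within_site"].iloc[0]
        assert within["se"] == pytest.approx(10.0 / np.sqrt(3), abs=1e-3)

    def test_among_site_se_and_zero_spread(self):
        df = pd.DataFrame({
            "site_id": ["S1"] * 2 + ["S2"] * 2 + ["S3"] * 2,
            "transect_id": list("ABCDEF"),
            "period": "w",
            "frequency_pct": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
        })
        out = variability_decomposition(df)
        among = out[out["level"] == "among_site"].iloc[0]
        assert among["se"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-3)
        assert (out[out["level"] == "within_site"]["se"] == 0.0).all()

    def test_single_member_level_missing(self):
        df = pd.DataFrame({"site_id": "S1", "transect_id": ["A"],
                           "period": "w", "frequency_pct": [10.0]})
        out = variability_decomposition(df)
        assert out["se"].isna().all()

    def test_textbook_sem_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.normal(size=rng.integers(2, 12))
            df = pd.DataFrame({"site_id": "S", "transect_id": range(len(v)),
                               "period": "p", "frequency_pct": v})
            got = variability_decomposition(df)
            got = got[got["level"] == "within_site"]["se"].iloc[0]
            exact = np.sqrt(((v - v.mean()) ** 2).sum() / (len(v) - 1)) / np.sqrt(len(v))
            assert got == pytest.approx(exact, abs=1e-12)


class TestMethodAgreement:
    def _status_with_monthly_freqs(self, islr_f, ep_f):
        frames = []
        for m, (fi, fe) in enumerate(zip(islr_f, ep_f)):
            times = pd.date_range(f"2021-{m + 1:02d}-01", periods=100, freq="h")
            df = _make_status([False] * 100, times)
            df["islr_present"] = np.arange(100) < fi
            df["endpoint_present"] = np.arange(100) < fe
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_identical_methods_give_unit_slope(self):
        status = self._status_with_monthly_freqs([10, 40, 80], [10, 40, 80])
        out = method_agreement(status)
        assert out["slope"] == pytest.approx(1.0) and out["r2"] == pytest.approx(1.0)

    def test_exact_scaling_recovered(self):
        status = self._status_with_monthly_freqs([10, 40, 80], [9, 36, 72])
        out = method_agreement(status)
        assert out["slope"] == pytest.approx(0.9) and out["r2"] == pytest.approx(1.0)

    def test_constant_predictor_undefined(self):
        status = self._status_with_monthly_freqs([50, 50, 50], [20, 30, 40])
        assert np.isnan(method_agreement(status)["slope"])

    def test_matches_brute_force_regression_on_synthetic_study(self, tiny_study):
        design, temps = tiny_study
        status = build_status_series(temps.plot_series, design)
        out = method_agreement(status)
        months = PeriodPartition.months()
        fi = frequency_by_period(status, months, "islr")
        fe = frequency_by_period(status, months, "endpoint")
        pair = fi[fi.scope == "transect"].merge(
            fe[fe.scope == "transect"], on=["transect_id", "period"])
        x = pair["frequency_pct_x"].to_numpy()
        y = pair["frequency_pct_y"].to_numpy()
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        r = np.corrcoef(x, y)[0, 1]
        assert out["slope"] == pytest.approx(slope, abs=1e-10)
        assert out["r2"] == pytest.approx(r ** 2, abs=1e-10)


def test_frequencies_invariant_to_timestep_order(tiny_study):
    design, temps = tiny_study
    status = build_status_series(temps.plot_series, design)
    shuffled = status.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = frequency_by_period(status, PeriodPartition.months())
    b = frequency_by_period(shuffled, PeriodPartition.months())
    key = ["scope", "site_id", "transect_id", "period"]
    a = a.sort_values(key).reset_index(drop=True)
    b = b.sort_values(key).reset_index(drop=True)
    assert np.allclose(a["frequency_pct"], b["frequency_pct"])
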