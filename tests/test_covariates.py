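import numpy as np
import pandas as pd
import pytest

from streamsync.covariates import (EnvironmentalDailySeries,
                                   build_covariate_table,
                                   cross_stream_average,
                                   joint_model_covariate, screen_collinearity,
                                   standardize, summarize_intervals)
from streamsync.data_model import OccasionCalendar


def daily(stream, start, temps, levels=None):
    n = len(temps)
    return EnvironmentalDailySeries(stream, pd.DataFrame({
        "date": pd.date_range(start, periods=n, freq="D"),
        "temp_c": temps,
        "level_m": levels if levels is not None else [0.2] * n}))


class TestSummarizeIntervals:
    def test_two_day_interval(self):
        cal = OccasionCalendar(pd.DatetimeIndex(["2016-01-01", "2016-01-03"]))
        s = daily("Indian", "2016-01-02", [10.0, 20.0])
        out = summarize_intervals(s, cal)
        assert out.loc[0, "mean_temp"] == 15.0
        assert out.loc[0, "max_temp"] == 20.0

    def test_constant_level(self):
        cal = OccasionCalendar(pd.DatetimeIndex(["2016-01-01", "2016-01-04"]))
        s = daily("Indian", "2016-01-02", [5.0, 5.0, 5.0], [0.2, 0.2, 0.2])
        out = summarize_intervals(s, cal)
        assert out.loc[0, "mean_level"] == pytest.approx(0.2)
        assert out.loc[0, "max_level"] == 0.2
        assert out.loc[0, "min_level"] == 0.2

    def test_missing_days_listed(self):
        cal = OccasionCalendar(pd.DatetimeIndex(["2016-01-01", "2016-01-05"]))
        s = daily("Indian", "2016-01-02", [5.0, 5.0])
        with pytest.raises(ValueError, match="2016-01-04"):
            summarize_intervals(s, cal)

    def test_matches_bruteforce_reaggregation(self, default_dataset):
        series = default_dataset["series"][0]
        cal = default_dataset["calendar"]
        out = summarize_intervals(series, cal)
        dates = series.data["date"].to_numpy(dtype="datetime64[D]")
        occ = cal.occasion_dates.values.astype("datetime64[D]")
        for t in range(cal.n_occasions - 1):
            picked = series.data[(dates > occ[t]) & (dates <= occ[t + 1])]
            assert out.loc[t, "mean_temp"] == pytest.approx(
                picked["temp_c"].mean(), abs=1e-12)
            assert out.loc[t, "min_level"] == pytest.approx(
                picked["level_m"].min(), abs=1e-12)

    def test_interval_partition(self, default_dataset):
        """Every day between first and last occasion is counted exactly once."""
        series = default_dataset["series"][0]
        cal = default_dataset["calendar"]
        dates = series.data["date"].to_numpy(dtype="datetime64[D]")
        occ = cal.occasion_dates.values.astype("datetime64[D]")
        counts = np.zeros(len(dates), dtype=int)
        for t in range(cal.n_occasions - 1):
            counts += ((dates > occ[t]) & (dates <= occ[t + 1])).astype(int)
        inside = (dates > occ[0]) & (dates <= occ[-1])
        assert (counts[inside] == 1).all()
        assert (counts[~inside] == 0).all()


class TestStandardize:
    def test_small_example(self):
        assert standardize([1, 2, 3]).tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self, rng):
        z = standardize(rng.normal(5, 3, 40))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_matches_formula(self, rng):
        x = rng.normal(2, 7, 25)
        np.testing.assert_allclose(
            standardize(x), (x - x.mean()) / x.std(ddof=1), atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([3.0, 3.0, 3.0])


class TestScreenCollinearity:
    def test_correlated_extreme_dropped(self, default_dataset):
        """Seasonal series make max temp track mean temp almost exactly, so
        the screen keeps the means and drops the extremes."""
        table = build_covariate_table(default_dataset["series"],
                                      default_dataset["calendar"])
        retained, corr = screen_collinearity(table)
        assert "mean_temp" in retained
        assert corr.loc["mean_temp", "max_temp"] > 0.9
        assert "max_temp" not in retained

    def test_duplicate_retained_once(self, default_dataset):
        table = build_covariate_table(default_dataset["series"],
                                      default_dataset["calendar"])
        # make max_temp an exact duplicate of mean_temp
        table.data["z_max_temp"] = table.data["z_mean_temp"]
        retained, corr = screen_collinearity(table)
        assert corr.loc["mean_temp", "max_temp"] == pytest.approx(1.0)
        assert "mean_temp" in retained and "max_temp" not in retained

    def test_orthogonal_both_retained(self, default_dataset):
        table = build_covariate_table(default_dataset["series"],
                                      default_dataset["calendar"])
        n = len(table.data)
        table.data["z_max_temp"] = standardize(
            np.resize([1.0, -1.0], n))  # alternating, ~uncorrelated
        retained, corr = screen_collinearity(table, threshold=0.5)
        if abs(corr.loc["mean_temp", "max_temp"]) <= 0.5:
            assert "max_temp" in retained

    def test_pearson_matches_covariance_ratio_oracle(self, default_dataset):
        table = build_covariate_table(default_dataset["series"],
                                      default_dataset["calendar"])
        _, corr = screen_collinearity(table)
        a = table.data["z_mean_temp"].to_numpy()
        b = table.data["z_mean_level"].to_numpy()
        r_oracle = (((a - a.mean()) * (b - b.mean())).sum()
                    / np.sqrt(((a - a.mean()) ** 2).sum()
                              * ((b - b.mean()) ** 2).sum()))
        assert corr.loc["mean_temp", "mean_level"] == pytest.approx(
            r_oracle, abs=1e-12)


class TestCrossStreamAverage:
    def test_elementwise_mean(self):
        np.testing.assert_array_equal(
            cross_stream_average([(1, 3), (3, 5)]), [2, 4])

    def test_identity_for_identical(self):
        np.testing.assert_array_equal(
            cross_stream_average([(1, 2), (1, 2)]), [1, 2])

    def test_three_streams(self):
        np.testing.assert_array_equal(
            cross_stream_average([(0, 0), (3, 3), (6, 9)]), [3, 4])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            cross_stream_average([(1, 2), (1, 2, 3)])


def test_joint_covariate_standardized(default_dataset):
    table = build_covariate_table(default_dataset["series"],
                                  default_dataset["calendar"])
    x = joint_model_covariate(table, "mean_temp")
    assert x.mean() == pytest.approx(0.0, abs=1e-12)
    assert x.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardized_columns_properties(default_dataset):
    table = build_covariate_table(default_dataset["series"],
                                  default_dataset["calendar"])
    for stream in table.streams():
        for name in ("mean_temp", "mean_level"):
            z = table.vector(stream, name)
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
    sub = table.data
    assert (sub["max_temp"] >= sub["mean_temp"]).all()
    assert (sub["max_level"] >= sub["mean_level"]).all()
    assert (sub["mean_level"] >= sub["min_level"]).all()


def test_daily_series_validation():
    with pytest.raises(ValueError, match="duplicate"):
        EnvironmentalDailySeries("x", pd.DataFrame({
            "date": ["2016-01-01", "2016-01-01"], "temp_c": [5, 5],
            "level_m": [0.2, 0.2]}))
    with pytest.raises(ValueError, match="level"):
        EnvironmentalDailySeries("x", pd.DataFrame({
            "date": ["2016-01-01"], "temp_c": [5], "level_m": [0.0]}))
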