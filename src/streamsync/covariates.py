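"""Per-interval environmental covariates for survival modelling.

Daily water-temperature and water-level logger series are summarized over
each interval between sampling occasions (half-open: a day belongs to
interval t when occasion_date[t] < day <= occasion_date[t+1], so every day
between the first and last occasion is counted exactly once), standardized
to mean 0 / sd 1, and screened for collinearity before entering the
logit-linear survival models.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_model import OccasionCalendar

#: covariate columns emitted per interval, in priority order for the
#: collinearity screen (means are preferred over extremes)
COVARIATE_NAMES = ("mean_temp", "mean_level", "max_temp", "max_level", "min_level")

TEMP_SANITY = (-5.0, 45.0)


@dataclasses.dataclass(eq=False)
class EnvironmentalDailySeries:
    """Daily mean water temperature (degC) and water level (m) for one stream."""

    stream: str
    data: pd.DataFrame  # columns: date, temp_c, level_m

    def __post_init__(self) -> None:
        for col in ("date", "temp_c", "level_m"):
            if col not in self.data.columns:
                raise ValueError(f"daily series missing column {col!r}")
        data = self.data.copy()
        data["date"] = pd.to_datetime(data["date"])
        if data["date"].duplicated().any():
            raise ValueError(f"duplicate dates in series for {self.stream}")
        if not data["date"].is_monotonic_increasing:
            raise ValueError(f"dates not increasing in series for {self.stream}")
        t = data["temp_c"].to_numpy()
        if ((t <= TEMP_SANITY[0]) | (t >= TEMP_SANITY[1])).any():
            raise ValueError(
                f"temperature outside sanity band {TEMP_SANITY} for {self.stream}")
        if (data["level_m"].to_numpy() <= 0).any():
            raise ValueError(f"non-positive water level for {self.stream}")
        self.data = data


@dataclasses.dataclass(eq=False)
class IntervalCovariateTable:
    """Raw and standardized per-interval covariates, one row per (stream, interval).

    Standardized columns are prefixed ``z_`` and have mean 0 / sample sd 1
    within each stream across the T-1 intervals.  ``retained`` is filled by
    the collinearity screen.
    """

    data: pd.DataFrame
    retained: tuple[str, ...] | None = None

    def streams(self) -> list[str]:
        return list(pd.unique(self.data["stream"]))

    def vector(self, stream: str, name: str, standardized: bool = True) -> np.ndarray:
        """Per-interval covariate vector for one stream, in interval order."""
        col = f"z_{name}" if standardized else name
        sub = self.data[self.data["stream"] == stream].sort_values("interval")
        if len(sub) == 0:
            raise KeyError(f"no rows for stream {stream!r}")
        return sub[col].to_numpy(dtype=float)


def summarize_intervals(series: EnvironmentalDailySeries,
                        calendar: OccasionCalendar) -> pd.DataFrame:
    """Summarize one stream's daily series into per-interval covariates.

    Returns one row per interval t = 1..T-1 with the five covariates
    (mean/max temperature, mean/max/min level).  Missing days inside any
    interval are a hard error.
    """
    dates = series.data["date"].to_numpy(dtype="datetime64[D]")
    occ = calendar.occasion_dates.values.astype("datetime64[D]")
    rows = []
    for t in range(calendar.n_occasions - 1):
        lo, hi = occ[t], occ[t + 1]
        mask = (dates > lo) & (dates <= hi)
        n_expected = int((hi - lo).astype(int))
        if mask.sum() == 0:
            raise ValueError(f"interval {t + 1}: no daily records in ({lo}, {hi}]")
        if mask.sum() < n_expected:
            have = set(dates[mask].astype("datetime64[D]").astype(str))
            want = [(lo + np.timedelta64(k + 1, "D")).astype(str)
                    for k in range(n_expected)]
            gaps = [d for d in want if d not in have]
            raise ValueError(f"interval {t + 1}: missing daily records {gaps}")
        temp = series.data.loc[mask, "temp_c"].to_numpy()
        lvl = series.data.loc[mask, "level_m"].to_numpy()
        rows.append({
            "stream": series.stream, "interval": t + 1,
            "mean_temp": temp.mean(), "max_temp": temp.max(),
            "mean_level": lvl.mean(), "max_level": lvl.max(),
            "min_level": lvl.min(),
        })
    return pd.DataFrame(rows)


def standardize(values, ddof: int = 1) -> np.ndarray:
    """Center and scale to mean 0, sd 1 (sample sd by default)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def build_covariate_table(series_list, calendar: OccasionCalendar,
                          ddof: int = 1) -> IntervalCovariateTable:
    """Summarize and standardize (per stream) all streams' daily series."""
    parts = []
    for series in series_list:
        part = summarize_intervals(series, calendar)
        for name in COVARIATE_NAMES:
            part[f"z_{name}"] = standardize(part[name].to_numpy(), ddof=ddof)
        parts.append(part)
    return IntervalCovariateTable(pd.concat(parts, ignore_index=True))


def screen_collinearity(table: IntervalCovariateTable, threshold: float = 0.5,
                        priority: tuple[str, ...] = ("mean_temp", "mean_level"),
                        use_absolute: bool = True):
    """Drop covariates strongly correlated with a higher-priority one.

    Covariates are visited in priority order (the ``priority`` names first,
    then the remaining covariates in their declared order); a covariate is
    retained only when its pairwise correlation with every already-retained
    covariate is at most ``threshold`` in magnitude (``use_absolute=False``
    compares the signed correlation instead).  Correlations are computed on
    the per-stream standardized columns pooled across streams.

    Returns ``(retained_names, correlation_matrix)`` and stores the
    retained list on the table.
    """
    names = [n for n in priority if n in COVARIATE_NAMES]
    names += [n for n in COVARIATE_NAMES if n not in names]
    z = table.data[[f"z_{n}" for n in names]].to_numpy(dtype=float)
    corr = np.corrcoef(z, rowvar=False)
    corr_df = pd.DataFrame(corr, index=names, columns=names)

    retained: list[str] = []
    for i, name in enumerate(names):
        r_with_kept = [corr_df.loc[name, k] for k in retained]
        vals = np.abs(r_with_kept) if use_absolute else np.array(r_with_kept)
        if len(retained) == 0 or (vals <= threshold).all():
            retained.append(name)
    table.retained = tuple(retained)
    return tuple(retained), corr_df


def cross_stream_average(x_by_stream) -> np.ndarray:
    """Elementwise mean of per-stream covariate vectors (any number of streams)."""
    vectors = [np.asarray(v, dtype=float) for v in x_by_stream]
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"covariate vectors differ in length: {sorted(lengths)}")
    return np.mean(vectors, axis=0)


def joint_model_covariate(table: IntervalCovariateTable, name: str,
                          ddof: int = 1) -> np.ndarray:
    """Covariate vector x_t for the joint (all-streams) synchrony model.

    The raw covariate is averaged across streams interval-by-interval and
    the average is then standardized, so x_t enters the joint model with
    mean 0 / sd 1.
    """
    raw = [table.vector(s, name, standardized=False) for s in table.streams()]
    return standardize(cross_stream_average(raw), ddof=ddof)


def read_daily_series(path) -> list[EnvironmentalDailySeries]:
    """Read a stacked per-stream daily CSV (stream,date,temp_c,level_m)."""
    table = pd.read_csv(path)
    for col in ("stream", "date", "temp_c", "level_m"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [EnvironmentalDailySeries(stream, sub.drop(columns="stream").reset_index(drop=True))
            for stream, sub in table.groupby("stream", sort=False)]


def write_daily_series(series_list, path) -> None:
    parts = []
    for s in series_list:
        part = s.data.copy()
        part.insert(0, "stream", s.stream)
        part["date"] = part["date"].dt.strftime("%Y-%m-%d")
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
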