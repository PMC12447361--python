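"""Heatwave detection and lagged exposure assembly from daily temperature series.

A heatwave is a run of at least ``min_duration`` consecutive days whose daily
mean temperature strictly exceeds a location-specific climatological
percentile threshold (92.5th, 95th or 97.5th).  Exposure for a survey record
is the vector of heatwave-day flags over the lags 0..L, where lag 0 is the
day *before* the interview (the 24-h recall day) and lag k is k days before
that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six (percentile, min_duration) combinations used as the canonical
#: multi-definition framework.
CANONICAL_DEFINITIONS = (
    (92.5, 2), (92.5, 3), (95.0, 2), (95.0, 3), (97.5, 2), (97.5, 3),
)


@dataclass(frozen=True)
class HeatwaveDefinition:
    """A (percentile, duration) heatwave rule.

    percentile is on the percent scale (e.g. 95.0); min_duration is the
    minimum number of consecutive exceedance days for a run to count.
    """

    percentile: float
    min_duration: int

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 100.0):
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.min_duration < 1:
            raise ValueError(f"min_duration must be >= 1, got {self.min_duration}")
        if not self.is_canonical:
            logger.warning(
                "non-canonical heatwave definition (%.1f, %d)",
                self.percentile, self.min_duration,
            )

    @property
    def is_canonical(self) -> bool:
        return (self.percentile, self.min_duration) in CANONICAL_DEFINITIONS

    @property
    def label(self) -> str:
        return f"p{self.percentile:g}_d{self.min_duration}"


@dataclass
class DailySeries:
    """Gap-free daily mean temperature series for one survey cluster."""

    cluster_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    tdew: np.ndarray | None = None
    precip: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) == 0:
            raise ValueError(f"cluster {self.cluster_id}: empty series")
        if len(self.dates) != len(self.tmean):
            raise ValueError(f"cluster {self.cluster_id}: dates/tmean length mismatch")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            raise ValueError(
                f"cluster {self.cluster_id}: dates must be strictly increasing and gap-free"
            )
        if not np.all(np.isfinite(self.tmean)):
            raise ValueError(f"cluster {self.cluster_id}: non-finite tmean values")
        for name in ("tdew", "precip"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.dates):
                    raise ValueError(f"cluster {self.cluster_id}: {name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def day_index(self, date) -> int:
        """Position of a calendar date in the series (may be out of range)."""
        return (pd.Timestamp(date) - self.start).days


@dataclass
class HeatwaveCalendar:
    """Per-day heatwave flags and events for one cluster under one definition."""

    cluster_id: str
    definition: HeatwaveDefinition
    threshold: float
    dates: pd.DatetimeIndex
    is_heatwave_day: np.ndarray
    events: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def flag(self, date) -> bool:
        i = (pd.Timestamp(date) - self.dates[0]).days
        if i < 0 or i >= len(self.dates):
            raise KeyError(f"date {date} outside calendar for cluster {self.cluster_id}")
        return bool(self.is_heatwave_day[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": self.cluster_id,
                "date": self.dates,
                "is_heatwave_day": self.is_heatwave_day.astype(int),
                "percentile": self.definition.percentile,
                "min_duration": self.definition.min_duration,
                "threshold_c": self.threshold,
            }
        )


def compute_threshold(
    series: DailySeries,
    percentile: float,
    climatology: tuple | None = None,
) -> float:
    """Climatological temperature threshold for one cluster.

    Empirical percentile (linear interpolation between order statistics, the
    "type 7" convention) of all daily means within the climatology window;
    by default the full series range (the compiled 2000-2020 record).
    ``percentile`` is on the percent scale.
    """
    vals = series.tmean
    if climatology is not None:
        lo, hi = pd.Timestamp(climatology[0]), pd.Timestamp(climatology[1])
        mask = (series.dates >= lo) & (series.dates <= hi)
        vals = vals[mask]
    if len(vals) == 0:
        raise ValueError(
            f"cluster {series.cluster_id}: empty climatology window for threshold"
        )
    return float(np.quantile(vals, percentile / 100.0, method="linear"))


def detect_heatwaves(
    series: DailySeries,
    definition: HeatwaveDefinition,
    threshold: float,
) -> HeatwaveCalendar:
    """Flag heatwave days: maximal runs of strict exceedance with length >= min_duration.

    "Exceeding" is read strictly: days exactly at the threshold do not count.
    """
    above = series.tmean > threshold
    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]  # ends exclusive
    flags = np.zeros(len(series), dtype=bool)
    events: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    for s, e in zip(starts, ends):
        if e - s >= definition.min_duration:
            flags[s:e] = True
            events.append((series.dates[s], series.dates[e - 1]))
    return HeatwaveCalendar(
        cluster_id=series.cluster_id,
        definition=definition,
        threshold=threshold,
        dates=series.dates,
        is_heatwave_day=flags,
        events=events,
    )


def lag_vector(calendar: HeatwaveCalendar, interview_date, max_lag: int = 14) -> np.ndarray:
    """Boolean exposure vector h[0..max_lag] for one interview date.

    h[k] is the heatwave flag for interview_date - 1 - k: lag 0 is the recall
    day (the day before the interview).
    """
    i0 = (pd.Timestamp(interview_date) - calendar.dates[0]).days
    lo = i0 - 1 - max_lag
    if lo < 0 or i0 - 1 >= len(calendar.dates):
        raise KeyError(
            f"cluster {calendar.cluster_id}: insufficient climate history for "
            f"interview {interview_date} at max_lag={max_lag}"
        )
    return calendar.is_heatwave_day[i0 - 1 - np.arange(max_lag + 1)].copy()


def build_lag_matrix(
    records: pd.DataFrame,
    calendars: dict[str, HeatwaveCalendar] | HeatwaveCalendar,
    max_lag: int = 14,
) -> pd.DataFrame:
    """Per-record lagged heatwave exposure matrix.

    records needs columns record_id, cluster_id, interview_date.  Records
    whose cluster calendar does not cover interview_date - 1 - max_lag are
    dropped with an itemised warning; the result is indexed by record_id with
    integer columns lag0..lag{max_lag}.
    """
    if isinstance(calendars, HeatwaveCalendar):
        calendars = {calendars.cluster_id: calendars}
    cols = [f"lag{k}" for k in range(max_lag + 1)]
    out = np.zeros((len(records), max_lag + 1), dtype=np.int8)
    ok = np.ones(len(records), dtype=bool)
    dates = pd.to_datetime(records["interview_date"])
    offsets = np.arange(max_lag + 1)
    for pos, (cid, date) in enumerate(zip(records["cluster_id"], dates)):
        cal = calendars.get(cid)
        if cal is None:
            ok[pos] = False
            continue
        i0 = (date - cal.dates[0]).days
        if i0 - 1 - max_lag < 0 or i0 - 1 >= len(cal.dates):
            ok[pos] = False
            continue
        out[pos] = cal.is_heatwave_day[i0 - 1 - offsets]
    n_dropped = int((~ok).sum())
    if n_dropped:
        bad = records.loc[~ok, "record_id"].tolist()
        logger.warning(
            "build_lag_matrix: dropped %d record(s) with insufficient climate "
            "history: %s", n_dropped, bad[:20],
        )
    return pd.DataFrame(out[ok], index=pd.Index(records.loc[ok, "record_id"],
                                                name="record_id"), columns=cols)


def annual_mean_temperature(series: DailySeries, interview_date) -> float:
    """Mean daily temperature over the 365 days ending the day before interview."""
    i0 = series.day_index(interview_date)
    lo = i0 - 365
    if lo < 0 or i0 - 1 >= len(series):
        raise ValueError(
            f"cluster {series.cluster_id}: fewer than 365 prior days before {interview_date}"
        )
    return float(series.tmean[lo:i0].mean())


def annual_mean_for_records(
    records: pd.DataFrame, series_by_cluster: dict[str, DailySeries]
) -> pd.Series:
    """Vectorised ``annual_mean_temperature`` for a records frame (record_id index)."""
    out = np.full(len(records), np.nan)
    dates = pd.to_datetime(records["interview_date"])
    for pos, (cid, date) in enumerate(zip(records["cluster_id"], dates)):
        s = series_by_cluster.get(cid)
        if s is None:
            continue
        i0 = s.day_index(date)
        if i0 - 365 >= 0 and i0 - 1 < len(s):
            out[pos] = s.tmean[i0 - 365:i0].mean()
    return pd.Series(out, index=records["record_id"].values, name="annual_mean_temp")


# Magnus saturation-vapour-pressure constants (hPa, degrees Celsius)
_MAGNUS_A, _MAGNUS_B, _MAGNUS_C = 6.112, 17.62, 243.12


def saturation_vapour_pressure(t_c):
    """Magnus formula e_s(T) = 6.112 * exp(17.62 T / (243.12 + T)), hPa."""
    t_c = np.asarray(t_c, dtype=float)
    return _MAGNUS_A * np.exp(_MAGNUS_B * t_c / (_MAGNUS_C + t_c))


def relative_humidity(tmean, tdew):
    """Relative humidity (%) from daily mean and dewpoint temperature.

    RH = 100 e_s(tdew) / e_s(tmean).  Dewpoints above the air temperature are
    clipped to it (RH capped at 100) with a warning.
    """
    tmean = np.asarray(tmean, dtype=float)
    tdew = np.asarray(tdew, dtype=float)
    if np.any(tdew > tmean):
        logger.warning(
            "relative_humidity: %d dewpoint value(s) above tmean clipped",
            int(np.sum(tdew > tmean)),
        )
        tdew = np.minimum(tdew, tmean)
    rh = 100.0 * saturation_vapour_pressure(tdew) / saturation_vapour_pressure(tmean)
    return rh if rh.ndim else float(rh)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_climate_csv(path) -> dict[str, DailySeries]:
    """Read long-format climate CSV (cluster_id, date, tmean_c[, tdew_c, precip_mm])."""
    df = pd.read_csv(path, parse_dates=["date"])
    return climate_frame_to_series(df)


def climate_frame_to_series(df: pd.DataFrame) -> dict[str, DailySeries]:
    """Split a long-format climate frame into per-cluster DailySeries."""
    out: dict[str, DailySeries] = {}
    for cid, g in df.groupby("cluster_id", sort=True):
        g = g.sort_values("date")
        out[str(cid)] = DailySeries(
            cluster_id=str(cid),
            dates=pd.DatetimeIndex(g["date"]),
            tmean=g["tmean_c"].to_numpy(),
            tdew=g["tdew_c"].to_numpy() if "tdew_c" in g else None,
            precip=g["precip_mm"].to_numpy() if "precip_mm" in g else None,
        )
    return out


def write_calendar_csv(calendars: dict[str, HeatwaveCalendar], path) -> None:
    pd.concat([c.to_frame() for c in calendars.values()], ignore_index=True).to_csv(
        path, index=False
    )


def extract_cluster_series_from_netcdf(
    nc_path, coords: pd.DataFrame, var: str = "tmean_c"
) -> dict[str, DailySeries]:
    """Nearest-grid-cell daily series extraction from a gridded NetCDF file.

    coords needs columns cluster_id, lat, lon; the dataset needs dims
    (time, lat, lon).  Uses the scipy NetCDF3 backend.
    """
    import xarray as xr

    ds = xr.open_dataset(nc_path, engine="scipy")
    out: dict[str, DailySeries] = {}
    for row in coords.itertuples(index=False):
        cell = ds[var].sel(lat=row.lat, lon=row.lon, method="nearest")
        out[str(row.cluster_id)] = DailySeries(
            cluster_id=str(row.cluster_id),
            dates=pd.DatetimeIndex(cell["time"].values),
            tmean=cell.values.astype(float),
        )
    ds.close()
    return out
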