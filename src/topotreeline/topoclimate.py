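"""Topoclimatic stress and amelioration indices from hourly meteorology.

Five indices summarise, per treeline location and month, the meteorological
combinations thought to damage or favour tree seedlings at the alpine
treeline:

* **photoinhibition** — cold, bright daytime hours (low temperature x high
  incoming shortwave) disrupt photosynthesis;
* **summer desiccation** — warm, windy, dry daytime air drives water loss
  from foliage and thin soils;
* **winter desiccation** — cold, windy, dry conditions over frozen soil
  ("frost drought"), averaged over the whole day;
* **frost** — cold, calm, strongly-radiating nights (negative net
  radiation) favouring radiative frost;
* **insolation** — total daytime shortwave input, the ameliorative term.

Temperatures (and, for frost, wind speeds) are reverse-scaled against the
site-level maximum so that values far below the site maximum weigh more;
relative humidity is reverse-scaled against 100 %.

The module also computes the per-month meteorological summary variables
(monthly extremes, frost hours, rain days, total solar, nighttime
longwave) that feed the multivariate ordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "HourlyMetSeries",
    "SiteMaxima",
    "DayNightPartition",
    "UndefinedIndexError",
    "partition_day_night",
    "site_maxima",
    "photoinhibition_index",
    "summer_desiccation_index",
    "winter_desiccation_index",
    "frost_index",
    "insolation",
    "monthly_summaries",
    "indices_table",
    "summaries_table",
    "write_hourly_csv",
    "read_hourly_csv",
]

MONTH_LABELS = ("jan", "jul")
DEFAULT_SOLAR_THRESHOLD = 1.0  # W/m2 separating day from night
FROST_TEMP_C = 0.0  # an hour below this counts as a frost hour
RAIN_DAY_MM = 0.1  # a day at/above this total counts as a rain day

#: month label -> calendar anchor used for CSV timestamps
_MONTH_START = {"jan": "2002-01-01", "jul": "2002-07-01"}


class UndefinedIndexError(ValueError):
    """An index's averaging hour set is empty; the value is undefined."""


@dataclass
class HourlyMetSeries:
    """One location's hourly meteorology for one month.

    Arrays all have length ``24 * n_days``; ``rain_mm`` holds daily totals
    (length ``n_days``).
    """

    site_id: str
    point_id: str
    month_label: str
    temp_c: np.ndarray
    wind_ms: np.ndarray
    rh_pct: np.ndarray
    solar_wm2: np.ndarray
    netrad_wm2: np.ndarray
    rain_mm: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        for name in ("temp_c", "wind_ms", "rh_pct", "solar_wm2", "netrad_wm2", "rain_mm"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.temp_c)
        for name in ("wind_ms", "rh_pct", "solar_wm2", "netrad_wm2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from temp_c")
        n_days = -(-n // 24)  # partial final day allowed for small series
        if self.rain_mm.size == 0:
            self.rain_mm = np.zeros(n_days)
        if len(self.rain_mm) != n_days:
            raise ValueError("rain_mm must hold one total per day")
        if np.any((self.rh_pct < 0) | (self.rh_pct > 100)):
            raise ValueError("relative humidity must lie in [0, 100] %")
        if np.any(self.solar_wm2 < 0):
            raise ValueError("incoming shortwave must be non-negative")

    @property
    def n_hours(self) -> int:
        return len(self.temp_c)

    @property
    def n_days(self) -> int:
        return -(-self.n_hours // 24)

    @property
    def hour_of_day(self) -> np.ndarray:
        return np.arange(self.n_hours) % 24


@dataclass(frozen=True)
class SiteMaxima:
    """Site-level maximum temperature and wind speed for one month."""

    site_id: str
    month_label: str
    t_site_max: float
    ws_site_max: float


@dataclass(frozen=True)
class DayNightPartition:
    """Boolean daytime mask for a series plus the hour counts."""

    daytime: np.ndarray
    n_daytime: int
    n_nighttime: int
    n_total: int


def partition_day_night(
    series: HourlyMetSeries, solar_threshold: float = DEFAULT_SOLAR_THRESHOLD
) -> DayNightPartition:
    """Split hours into day and night by an irradiance threshold.

    An hour is daytime when incoming shortwave exceeds ``solar_threshold``
    (default 1 W/m2 — effectively "the sun is up" while tolerating sensor
    or model noise around zero).
    """
    day = series.solar_wm2 > solar_threshold
    n_day = int(day.sum())
    return DayNightPartition(day, n_day, series.n_hours - n_day, series.n_hours)


def site_maxima(series_collection: Iterable[HourlyMetSeries]) -> SiteMaxima:
    """Maximum temperature and wind speed over every hour of every
    location in one site-month."""
    series_list = list(series_collection)
    if not series_list:
        raise ValueError("site_maxima requires at least one series")
    site = series_list[0].site_id
    month = series_list[0].month_label
    for s in series_list:
        if s.site_id != site or s.month_label != month:
            raise ValueError("all series must share site_id and month_label")
    return SiteMaxima(
        site_id=site,
        month_label=month,
        t_site_max=float(max(s.temp_c.max() for s in series_list)),
        ws_site_max=float(max(s.wind_ms.max() for s in series_list)),
    )


def photoinhibition_index(
    series: HourlyMetSeries, maxima: SiteMaxima, partition: DayNightPartition
) -> float:
    """Mean daytime product of reverse-scaled temperature and shortwave.

    sum_daytime[(T_site_max - T_hourly) * SolRad_hourly] / N_daytime.
    Units: degC * W/m2.
    """
    if partition.n_daytime == 0:
        raise UndefinedIndexError("photoinhibition undefined: no daytime hours")
    day = partition.daytime
    total = np.sum((maxima.t_site_max - series.temp_c[day]) * series.solar_wm2[day])
    return float(total / partition.n_daytime)


def summer_desiccation_index(
    series: HourlyMetSeries, partition: DayNightPartition
) -> float:
    """Mean daytime product of temperature, wind and humidity deficit.

    sum_daytime[T_hourly * WS_hourly * (100 - RelHum_hourly)] / N_daytime.
    Units: degC * (m/s) * %. May be negative under sub-zero daytime
    temperatures; no floor is applied.
    """
    if partition.n_daytime == 0:
        raise UndefinedIndexError("summer desiccation undefined: no daytime hours")
    day = partition.daytime
    total = np.sum(
        series.temp_c[day] * series.wind_ms[day] * (100.0 - series.rh_pct[day])
    )
    return float(total / partition.n_daytime)


def winter_desiccation_index(
    series: HourlyMetSeries,
    maxima: SiteMaxima,
    partition: DayNightPartition,
    hour_set: Literal["all_hours", "daytime_only"] = "all_hours",
) -> float:
    """Whole-day mean of reverse-scaled temperature x wind x humidity deficit.

    sum[(T_site_max - T_hourly) * WS_hourly * (100 - RelHum_hourly)] / N_total,
    summed over all hours by default. ``hour_set="daytime_only"`` restricts
    the numerator sum to daytime hours (the denominator stays N_total);
    both conventions are defensible readings of the index and both are
    exposed.
    """
    if partition.n_total == 0:
        raise UndefinedIndexError("winter desiccation undefined: empty series")
    if hour_set == "all_hours":
        sel = np.ones(series.n_hours, dtype=bool)
    elif hour_set == "daytime_only":
        sel = partition.daytime
        if not sel.any():
            raise UndefinedIndexError(
                "winter desiccation (daytime_only) undefined: no daytime hours"
            )
    else:
        raise ValueError("hour_set must be 'all_hours' or 'daytime_only'")
    total = np.sum(
        (maxima.t_site_max - series.temp_c[sel])
        * series.wind_ms[sel]
        * (100.0 - series.rh_pct[sel])
    )
    return float(total / partition.n_total)


def frost_index(
    series: HourlyMetSeries, maxima: SiteMaxima, partition: DayNightPartition
) -> float:
    """Mean nighttime radiative-frost potential.

    sum_nighttime[(T_site_max - T_hourly) * (WS_site_max - WS_hourly)
    * (-NetRad_hourly)] / N_nighttime. Nights that are cold, calm and
    strongly radiating (net radiation negative) score highest.
    """
    if partition.n_nighttime == 0:
        raise UndefinedIndexError("frost index undefined: no nighttime hours")
    night = ~partition.daytime
    total = np.sum(
        (maxima.t_site_max - series.temp_c[night])
        * (maxima.ws_site_max - series.wind_ms[night])
        * (-series.netrad_wm2[night])
    )
    return float(total / partition.n_nighttime)


def insolation(series: HourlyMetSeries, partition: DayNightPartition) -> float:
    """Total daytime incoming shortwave for the month (W h / m2)."""
    return float(np.sum(series.solar_wm2[partition.daytime]))


def monthly_summaries(
    series: HourlyMetSeries, partition: DayNightPartition
) -> dict[str, float]:
    """The ten per-month meteorological summary variables.

    Absolute monthly extremes of temperature, wind and humidity, frost
    hours (T < 0 degC), rain days (daily total >= 0.1 mm), total daytime
    solar radiation and mean nighttime net outgoing longwave (positive).
    Raises :class:`UndefinedIndexError` if the longwave summary has no
    nighttime hours to average.
    """
    if partition.n_nighttime == 0:
        raise UndefinedIndexError(
            "net outgoing longwave undefined: no nighttime hours"
        )
    night = ~partition.daytime
    return {
        "temp_min": float(series.temp_c.min()),
        "temp_max": float(series.temp_c.max()),
        "wind_min": float(series.wind_ms.min()),
        "wind_max": float(series.wind_ms.max()),
        "rh_min": float(series.rh_pct.min()),
        "rh_max": float(series.rh_pct.max()),
        "frost_hours": float(np.sum(series.temp_c < FROST_TEMP_C)),
        "rain_days": float(np.sum(series.rain_mm >= RAIN_DAY_MM)),
        "total_solar": insolation(series, partition),
        "net_longwave": float(np.mean(-series.netrad_wm2[night])),
    }


# ---------------------------------------------------------------------------
# Tabular drivers
# ---------------------------------------------------------------------------


def _group_site_month(series_list: Iterable[HourlyMetSeries]):
    groups: dict[tuple[str, str], list[HourlyMetSeries]] = {}
    for s in series_list:
        groups.setdefault((s.site_id, s.month_label), []).append(s)
    return groups


def indices_table(
    series_list: Iterable[HourlyMetSeries],
    solar_threshold: float = DEFAULT_SOLAR_THRESHOLD,
    winter_hour_set: Literal["all_hours", "daytime_only"] = "all_hours",
) -> pd.DataFrame:
    """Compute all five indices for every series.

    The desiccation column carries the summer form for January and the
    winter form for July. Site maxima are taken per site x month over all
    locations.
    """
    rows = []
    for (site, month), group in _group_site_month(series_list).items():
        maxima = site_maxima(group)
        for s in group:
            part = partition_day_night(s, solar_threshold)
            if month == "jan":
                desic = summer_desiccation_index(s, part)
            else:
                desic = winter_desiccation_index(s, maxima, part, winter_hour_set)
            rows.append(
                {
                    "point_id": s.point_id,
                    "site_id": site,
                    "month": month,
                    "photoinhibition": photoinhibition_index(s, maxima, part),
                    "desiccation": desic,
                    "frost": frost_index(s, maxima, part),
                    "insolation": insolation(s, part),
                }
            )
    return pd.DataFrame(rows)


def summaries_table(
    series_list: Iterable[HourlyMetSeries],
    solar_threshold: float = DEFAULT_SOLAR_THRESHOLD,
) -> pd.DataFrame:
    """Wide per-point table of the 20 monthly summary variables.

    Columns are ``<month>_<variable>`` (e.g. ``jan_total_solar``,
    ``jul_frost_hours``) for the ten summaries of each of the two months;
    one row per point that has both months.
    """
    long_rows = []
    for s in series_list:
        part = partition_day_night(s, solar_threshold)
        rec = monthly_summaries(s, part)
        rec.update(point_id=s.point_id, site_id=s.site_id, month=s.month_label)
        long_rows.append(rec)
    long = pd.DataFrame(long_rows)
    wide = long.pivot(index=["point_id", "site_id"], columns="month")
    wide.columns = [f"{month}_{var}" for var, month in wide.columns]
    return wide.dropna(axis=0).reset_index()


# ---------------------------------------------------------------------------
# Long-format CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "site_id",
    "point_id",
    "timestamp_hour",
    "temp_c",
    "wind_ms",
    "rh_pct",
    "solar_wm2",
    "netrad_wm2",
    "rain_mm",
]


def write_hourly_csv(series_list: Iterable[HourlyMetSeries], path) -> None:
    """Write series as long-format CSV.

    ``rain_mm`` repeats each day's total on every hour of that day;
    timestamps anchor January to 2002-01 and July to 2002-07 (the model
    year the series emulate).
    """
    frames = []
    for s in series_list:
        stamps = pd.date_range(
            _MONTH_START[s.month_label], periods=s.n_hours, freq="h"
        )
        frames.append(
            pd.DataFrame(
                {
                    "site_id": s.site_id,
                    "point_id": s.point_id,
                    "timestamp_hour": stamps,
                    "temp_c": s.temp_c,
                    "wind_ms": s.wind_ms,
                    "rh_pct": s.rh_pct,
                    "solar_wm2": s.solar_wm2,
                    "netrad_wm2": s.netrad_wm2,
                    "rain_mm": np.repeat(s.rain_mm, 24)[: s.n_hours],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_hourly_csv(path) -> list[HourlyMetSeries]:
    """Read series written by :func:`write_hourly_csv`."""
    df = pd.read_csv(path, parse_dates=["timestamp_hour"])
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hourly CSV missing columns: {', '.join(missing)}")
    df["month_label"] = df["timestamp_hour"].dt.month.map({1: "jan", 7: "jul"})
    out = []
    for (site, point, month), g in df.groupby(
        ["site_id", "point_id", "month_label"], sort=True
    ):
        g = g.sort_values("timestamp_hour")
        out.append(
            HourlyMetSeries(
                site_id=str(site),
                point_id=str(point),
                month_label=month,
                temp_c=g["temp_c"].to_numpy(),
                wind_ms=g["wind_ms"].to_numpy(),
                rh_pct=g["rh_pct"].to_numpy(),
                solar_wm2=g["solar_wm2"].to_numpy(),
                netrad_wm2=g["netrad_wm2"].to_numpy(),
                rain_mm=g["rain_mm"].to_numpy()[::24],
            )
        )
    return out
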