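"""Seeded synthetic data emulating mountain study areas.

Every downstream stage — landform operators, topoclimatic indices,
ordination, tree-based modelling — is exercised against data produced
here, so each generator is deterministic given its seed and produces
physically sane output (bounded humidity, non-negative wind and
shortwave, negative nighttime net radiation).

The generators emulate the structure of mesoscale-atmospheric-model
output for 7 x 7 km mountain study areas on a 200 m grid: hourly
January and July meteorology with realistic diurnal cycles, an
elevational temperature lapse, wind that increases with topographic
exposure, and day/night radiation sign structure. They make no attempt
at real atmospheric dynamics (no advection, no cold-air drainage).

Treeline points carry a *known* deviation-generating function
(:class:`EffectSpec`), so regression, importance-ranking and
split-threshold recovery can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .landform import DEMGrid, curvature, slope_percent
from .topoclimate import HourlyMetSeries

__all__ = [
    "TerrainSpec",
    "MetSpec",
    "EffectSpec",
    "DAYLIGHT_WINDOWS",
    "generate_dem",
    "generate_hourly_met",
    "generate_treeline_points",
    "generate_regional_covariates",
    "generate_feature_table",
    "study_area_spec",
    "EXPLANATORY_COLUMNS",
]

#: daylight window per month, [start_hour, end_hour): Southern-Hemisphere
#: seasonality at ~39-46 deg S — long January days, short July days.
DAYLIGHT_WINDOWS = {"jan": (6, 21), "jul": (8, 17)}

#: the 17 explanatory variables of the treeline feature table
EXPLANATORY_COLUMNS = [
    "curvature",
    "slope_percent",
    "photoinhibition_jan",
    "photoinhibition_jul",
    "desiccation_jan",
    "desiccation_jul",
    "frost_jan",
    "frost_jul",
    "insolation_jan",
    "insolation_jul",
    "growing_season_temp",
    "annual_precipitation",
    "mountain_mass_index",
    "earthquake_intensity",
    "erosion_index",
    "winter_temp_min",
    "winter_temp_max",
]

#: plausible ranges used when a named covariate must be invented
_COVARIATE_RANGES = {
    "curvature": (-1.5, 1.5),
    "slope_percent": (0.0, 150.0),
    "photoinhibition_jan": (0.0, 8000.0),
    "photoinhibition_jul": (0.0, 4000.0),
    "desiccation_jan": (0.0, 6000.0),
    "desiccation_jul": (0.0, 3000.0),
    "frost_jan": (0.0, 20000.0),
    "frost_jul": (0.0, 50000.0),
    "insolation_jan": (100000.0, 300000.0),
    "insolation_jul": (30000.0, 100000.0),
    "growing_season_temp": (9.0, 14.0),
    "annual_precipitation": (1000.0, 9000.0),
    "mountain_mass_index": (0.0, 49.0),
    "earthquake_intensity": (0.0, 1.0),
    "erosion_index": (0.0, 10.0),
    "winter_temp_min": (-15.0, -2.0),
    "winter_temp_max": (2.0, 12.0),
}


class GenerationError(RuntimeError):
    """A generator's preconditions were met but no output could be built."""


@dataclass(frozen=True)
class TerrainSpec:
    """Parameters of a synthetic ridge-and-valley DEM."""

    n_rows: int = 35
    n_cols: int = 35
    cell_size: float = 200.0
    base_elevation: float = 900.0
    relief_amplitude: float = 600.0
    ridge_wavelength: float = 2800.0
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("terrain requires at least a 3x3 grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.relief_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("relief_amplitude and noise_sd must be >= 0")
        if self.ridge_wavelength <= 0:
            raise ValueError("ridge_wavelength must be positive")


def study_area_spec(extent_km: float = 7.0, cell_size: float = 200.0, **kw) -> TerrainSpec:
    """Terrain spec for a square study area of the given extent.

    The default 7 km x 7 km area at 200 m resolution gives the 35 x 35 =
    1,225 cells of one atmospheric-model study domain.
    """
    n = int(round(extent_km * 1000.0 / cell_size))
    return TerrainSpec(n_rows=n, n_cols=n, cell_size=cell_size, **kw)


def generate_dem(spec: TerrainSpec) -> DEMGrid:
    """Synthesise a DEM of superposed sinusoidal ridges plus noise.

    The smooth component is a sum of sinusoids along both axes at
    ``ridge_wavelength``, rescaled so its sampled relief is exactly
    ``relief_amplitude``; Gaussian cell noise (sd ``noise_sd``) is added
    on top. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.n_cols) * spec.cell_size
    y = np.arange(spec.n_rows) * spec.cell_size
    xx, yy = np.meshgrid(x, y)
    s = np.sin(2 * np.pi * xx / spec.ridge_wavelength) + np.sin(
        2 * np.pi * yy / spec.ridge_wavelength
    )
    span = s.max() - s.min()
    if spec.relief_amplitude > 0 and span > 0:
        smooth = spec.base_elevation + spec.relief_amplitude * (s - s.min()) / span
    else:
        smooth = np.full_like(s, spec.base_elevation)
    z = smooth + rng.normal(0.0, spec.noise_sd, size=s.shape)
    return DEMGrid(values=z, cell_size=spec.cell_size)


@dataclass(frozen=True)
class MetSpec:
    """Parameters of one month's synthetic hourly meteorology.

    Noise terms are Gaussian and independent across hours — the simplest
    structure the indices require; there is no temporal autocorrelation
    beyond the diurnal cycle. Rain is generated per day (only rain-day
    counts are consumed downstream).
    """

    month_label: str = "jan"
    n_days: int = 31
    mean_temp_at_base: float = 14.0
    diurnal_range: float = 9.0
    lapse_rate: float = 0.006  # degC per m
    mean_wind: float = 4.0
    wind_exposure_gain: float = 0.015  # m/s per m of relative elevation
    rh_mean: float = 75.0
    rh_diurnal_range: float = 25.0
    solar_peak: float = 950.0
    cloud_fraction: float = 0.35
    nocturnal_longwave: float = 70.0  # positive magnitude, W/m2
    wet_day_prob: float = 0.35
    rain_gamma_shape: float = 1.3
    rain_gamma_scale: float = 8.0
    temp_noise_sd: float = 1.0
    wind_noise_sd: float = 0.8
    rh_noise_sd: float = 5.0
    solar_exposure_range: float = 0.15  # per-location aspect factor, +/-
    daily_weather_range: float = 0.3  # day-to-day cloud/longwave factor, +/-
    seed: int = 0

    def __post_init__(self) -> None:
        if self.month_label not in DAYLIGHT_WINDOWS:
            raise ValueError("month_label must be 'jan' or 'jul'")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must lie in [0, 1]")
        if not 0.0 < self.rh_mean <= 100.0:
            raise ValueError("rh_mean must lie in (0, 100]")
        if self.solar_peak <= 0 or self.nocturnal_longwave <= 0:
            raise ValueError("solar_peak and nocturnal_longwave must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @classmethod
    def january(cls, **kw) -> "MetSpec":
        """Mid-summer month: warm, long days, strong sun."""
        defaults = dict(month_label="jan", n_days=31)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def july(cls, **kw) -> "MetSpec":
        """Mid-winter month: cold, short days, weak sun."""
        defaults = dict(
            month_label="jul",
            n_days=31,
            mean_temp_at_base=3.0,
            diurnal_range=7.0,
            mean_wind=5.5,
            rh_mean=80.0,
            solar_peak=450.0,
            cloud_fraction=0.45,
            nocturnal_longwave=60.0,
            wet_day_prob=0.45,
        )
        defaults.update(kw)
        return cls(**defaults)


def _relative_elevation(dem: DEMGrid, window: int = 5) -> np.ndarray:
    """Elevation minus the local mean in a window x window neighbourhood
    (edge-truncated) — a simple topographic-exposure measure."""
    z = dem.masked()
    filled = np.where(np.isfinite(z), z, np.nanmean(z))
    return filled - uniform_filter(filled, size=window, mode="nearest")


def generate_hourly_met(
    dem: DEMGrid, spec: MetSpec, locations: pd.DataFrame
) -> list[HourlyMetSeries]:
    """Generate one month of hourly meteorology per location.

    ``locations`` needs ``point_id``, ``site_id``, ``easting`` and
    ``northing`` columns and all points must fall inside the DEM extent.

    Construction, per hour-of-day ``h`` and location elevation ``z``:

    * temperature: ``mean_temp_at_base - lapse_rate*(z - z_ref)`` plus a
      cosine diurnal cycle peaking at 15:00 plus Gaussian noise, with
      ``z_ref`` the DEM minimum;
    * shortwave: a half-sine over the month's daylight window, sampled at
      mid-hour so every daylight hour is strictly positive, scaled by
      ``solar_peak * (1 - cloud_fraction)`` times a per-location aspect
      exposure factor and a per-day weather factor (emulating aspect
      differences and day-to-day cloudiness); exactly 0 at night;
    * net radiation: shortwave minus a nocturnal longwave magnitude that
      varies day to day with the weather factor — strictly negative at
      night;
    * relative humidity: anti-phase with temperature, plus noise, clipped
      to [5, 100] %;
    * wind: ``mean_wind + wind_exposure_gain * relative elevation`` (5x5
      window) plus noise, floored at 0;
    * rain: daily Bernoulli(wet_day_prob) x Gamma(shape, scale) totals.

    Deterministic given ``spec.seed``; each location's draw depends only
    on its positional index.
    """
    from .landform import _point_cell  # nearest-cell rule shared with extraction

    required = {"point_id", "site_id", "easting", "northing"}
    missing = required - set(locations.columns)
    if missing:
        raise ValueError(f"locations missing columns: {', '.join(sorted(missing))}")

    z = dem.masked()
    z_ref = float(np.nanmin(z))
    rel_elev = _relative_elevation(dem)

    start, end = DAYLIGHT_WINDOWS[spec.month_label]
    duration = end - start
    n_hours = 24 * spec.n_days
    hod = np.arange(n_hours) % 24
    mid = hod + 0.5
    in_day = (mid >= start) & (mid < end)
    solar_shape = np.where(
        in_day, np.sin(np.pi * (mid - start) / duration), 0.0
    )
    solar_base = spec.solar_peak * (1.0 - spec.cloud_fraction) * solar_shape
    diurnal = np.cos(2 * np.pi * (hod - 15) / 24.0)
    w = spec.daily_weather_range

    out: list[HourlyMetSeries] = []
    for i, (_, rec) in enumerate(locations.iterrows()):
        try:
            r, c = _point_cell(dem, float(rec["easting"]), float(rec["northing"]))
        except ValueError:
            raise ValueError(
                f"location {rec['point_id']!r} lies outside the DEM extent"
            ) from None
        elev = z[r, c]
        if not np.isfinite(elev):
            elev = z_ref
        rng = np.random.default_rng([spec.seed, i])
        exposure = rng.uniform(
            1.0 - spec.solar_exposure_range, 1.0 + spec.solar_exposure_range
        )
        day_factor = rng.uniform(1.0 - w, 1.0 + w, spec.n_days)
        solar = solar_base * exposure * np.repeat(day_factor, 24)
        longwave_daily = spec.nocturnal_longwave * rng.uniform(
            1.0 - w / 2.0, 1.0 + w / 2.0, spec.n_days
        )
        netrad = solar - np.repeat(longwave_daily, 24)
        temp = (
            spec.mean_temp_at_base
            - spec.lapse_rate * (elev - z_ref)
            + 0.5 * spec.diurnal_range * diurnal
            + rng.normal(0.0, spec.temp_noise_sd, n_hours)
        )
        rh = np.clip(
            spec.rh_mean
            - 0.5 * spec.rh_diurnal_range * diurnal
            + rng.normal(0.0, spec.rh_noise_sd, n_hours),
            5.0,
            100.0,
        )
        wind = np.maximum(
            spec.mean_wind
            + spec.wind_exposure_gain * rel_elev[r, c]
            + rng.normal(0.0, spec.wind_noise_sd, n_hours),
            0.0,
        )
        wet = rng.random(spec.n_days) < spec.wet_day_prob
        amounts = rng.gamma(spec.rain_gamma_shape, spec.rain_gamma_scale, spec.n_days)
        rain = np.where(wet, amounts, 0.0)
        out.append(
            HourlyMetSeries(
                site_id=str(rec["site_id"]),
                point_id=str(rec["point_id"]),
                month_label=spec.month_label,
                temp_c=temp,
                wind_ms=wind,
                rh_pct=rh,
                solar_wm2=solar,
                netrad_wm2=netrad,
                rain_mm=rain,
            )
        )
    return out


@dataclass(frozen=True)
class EffectSpec:
    """A known deviation-generating function for parameter recovery.

    deviation = intercept + beta_curvature*curvature
    + beta_slope*slope_percent + sum(beta_index[v] * v)
    + sum(step for (v, threshold, step) with v > threshold)
    + Gaussian(0, noise_sd), clipped below at 0.
    """

    intercept: float = 150.0
    beta_curvature: float = 0.0
    beta_slope: float = 0.0
    beta_index: dict = field(default_factory=dict)
    threshold_terms: Sequence[tuple[str, float, float]] = ()
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def variables(self) -> list[str]:
        """All feature names the effect function consumes."""
        names = ["curvature", "slope_percent"]
        names += list(self.beta_index)
        names += [v for v, _, _ in self.threshold_terms]
        # preserve order, drop duplicates
        return list(dict.fromkeys(names))

    def mean_response(self, features: pd.DataFrame) -> np.ndarray:
        """Noise-free deviation for each row of ``features``."""
        dev = np.full(len(features), self.intercept, dtype=float)
        if self.beta_curvature:
            dev += self.beta_curvature * features["curvature"].to_numpy()
        if self.beta_slope:
            dev += self.beta_slope * features["slope_percent"].to_numpy()
        for name, beta in self.beta_index.items():
            dev += beta * features[name].to_numpy()
        for name, threshold, step in self.threshold_terms:
            dev += step * (features[name].to_numpy() > threshold)
        return dev

    def response(self, features: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        dev = self.mean_response(features)
        if self.noise_sd > 0:
            dev = dev + rng.normal(0.0, self.noise_sd, len(dev))
        return np.maximum(dev, 0.0)


def _draw_covariates(
    names: Sequence[str], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name in names:
        lo, hi = _COVARIATE_RANGES.get(name, (0.0, 1.0))
        cols[name] = rng.uniform(lo, hi, n)
    return pd.DataFrame(cols)


def generate_treeline_points(
    dem: DEMGrid,
    effect: EffectSpec,
    n_points: int,
    site_id: str,
    covariates: Optional[pd.DataFrame] = None,
    band_quantile: float = 0.75,
) -> pd.DataFrame:
    """Place treeline points along the DEM's upper elevation band.

    Points are drawn from interior cells at or above the
    ``band_quantile`` elevation quantile; each point's true deviation is
    computed from :class:`EffectSpec` using the local curvature and
    slope (and any named covariates — supplied via ``covariates`` or
    drawn from plausible ranges). The realized point elevation is the
    band maximum minus the deviation, floored at the DEM minimum.

    Returns a DataFrame with point coordinates, realized ``elevation``,
    ``deviation_true`` and every feature column the effect consumed; the
    generating spec is attached as ``.attrs["effect"]``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    slope = slope_percent(dem).masked()
    curv = curvature(dem).masked()
    z = dem.masked()
    valid = np.isfinite(z) & np.isfinite(slope) & np.isfinite(curv)
    if not valid.any():
        raise GenerationError("DEM has no interior cells to sample")
    band_floor = np.nanquantile(z[valid], band_quantile)
    band = valid & (z >= band_floor)
    if not band.any():
        raise GenerationError("target elevation band is empty")
    rows, cols = np.nonzero(band)
    rng = np.random.default_rng(effect.seed)
    pick = rng.choice(len(rows), size=n_points, replace=len(rows) < n_points)
    r, c = rows[pick], cols[pick]

    feats = pd.DataFrame(
        {"curvature": curv[r, c], "slope_percent": slope[r, c]}
    )
    extra = [v for v in effect.variables() if v not in feats.columns]
    if extra:
        drawn = _draw_covariates(extra, n_points, rng)
        if covariates is not None:
            for name in extra:
                if name in covariates.columns:
                    drawn[name] = np.asarray(covariates[name])[:n_points]
        feats = pd.concat([feats, drawn], axis=1)

    deviation = effect.response(feats, rng)
    band_max = float(np.nanmax(z[band]))
    z_min = float(np.nanmin(z[valid]))
    elevation = np.maximum(band_max - deviation, z_min)

    east = dem.origin_easting + (c + 0.5) * dem.cell_size
    north = dem.origin_northing + (dem.n_rows - r - 0.5) * dem.cell_size
    out = pd.DataFrame(
        {
            "point_id": [f"{site_id}_p{k:04d}" for k in range(n_points)],
            "site_id": site_id,
            "easting": east,
            "northing": north,
            "elevation": elevation,
            "deviation_true": deviation,
        }
    )
    out = pd.concat([out, feats], axis=1)
    out.attrs["effect"] = effect
    return out


def generate_regional_covariates(n_sites: int, seed: int = 0) -> pd.DataFrame:
    """Per-site regional covariates drawn from plausible ranges.

    Growing-season temperature 9-14 degC, annual precipitation
    1,000-9,000 mm, earthquake intensity 0-1 (proportion of g) and a
    non-negative erosion index; deterministic given ``seed``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    names = [
        "growing_season_temp",
        "annual_precipitation",
        "earthquake_intensity",
        "erosion_index",
    ]
    table = _draw_covariates(names, n_sites, rng)
    table.insert(0, "site_id", [f"site{k:02d}" for k in range(n_sites)])
    return table


def generate_feature_table(
    n_points: int, effect: EffectSpec, seed: int = 0
) -> pd.DataFrame:
    """A full treeline feature table with known effect structure.

    Draws all 17 explanatory variables independently from plausible
    ranges and computes ``elevation_deviation`` from ``effect``; used to
    test importance ranking, partial dependence and split recovery
    against ground truth. Deterministic given ``seed`` (the effect's own
    seed is ignored here so one effect can generate many replicates).
    """
    rng = np.random.default_rng(seed)
    table = _draw_covariates(EXPLANATORY_COLUMNS, n_points, rng)
    # curvature centred on 0 so convex/concave splits are exercised
    table["curvature"] = rng.normal(0.0, 0.5, n_points)
    table["elevation_deviation"] = effect.response(table, rng)
    return table
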