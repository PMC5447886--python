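"""Synthetic daily weather for tropical, subtropical and temperate rice sites.

Stands in for multi-decade station records: each site archetype is a
seasonal sinusoid (temperature, humidity) plus AR(1) daily anomalies, with
daily global radiation generated as a stochastic clearness index times the
extraterrestrial radiation from standard solar geometry.  A climate
transform produces the mid-century scenario: +2.0 degC on both temperature
extremes, ambient CO2 550 umol mol-1, vapour pressure rescaled to preserve
relative humidity.

The three shipped archetypes follow the latitudes of Los Banos (14.1 N,
tropical), Nanjing (32.9 N, subtropical) and Shizukuishi (39.7 N,
temperate), with the per-site phenology calibration (thermal-day
requirements and emergence day) they were run with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import saturated_vp

SOLAR_CONSTANT = 1367.0  # W m-2
CO2_PRESENT = 400.0      # umol mol-1
CO2_2050 = 550.0
WARMING_2050 = 2.0       # degC


@dataclass
class PhenologyParams:
    """Cardinal temperatures and thermal-day requirements of the crop."""

    t_base: float = 8.0      # degC
    t_opt: float = 30.0
    t_ceil: float = 42.0
    m_v: float = 70.0        # thermal days, emergence -> flowering
    m_r: float = 28.0        # thermal days, flowering -> maturity
    start_day: int = 10      # day of year of seedling emergence

    def __post_init__(self):
        if not self.t_base < self.t_opt < self.t_ceil:
            raise ValueError("cardinal temperatures must satisfy Tb < To < Tc")
        if self.m_v <= 0 or self.m_r <= 0:
            raise ValueError("thermal-day requirements must be positive")


@dataclass
class SiteConfig:
    """Climatology of one site archetype plus its crop calendar."""

    name: str
    latitude: float              # degrees
    t_mean: float                # annual mean air temperature, degC
    t_amplitude: float           # seasonal half-amplitude, degC
    diurnal_range: float         # mean tmax - tmin, degC
    clearness_mean: float        # mean daily clearness index (0, 0.8]
    clearness_sd: float
    rh_mean: float               # mean relative humidity (0-1)
    wind_mean: float             # m s-1
    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    t_phase_doy: int = 200       # day of year of the warmest day

    def __post_init__(self):
        if not -60.0 <= self.latitude <= 60.0:
            raise ValueError("latitude outside [-60, 60]")
        if not 0.0 < self.clearness_mean <= 0.8:
            raise ValueError("clearness outside (0, 0.8]")


def tropical_site() -> SiteConfig:
    """Los Banos-like archetype (dry-season crop, emergence day 10)."""
    return SiteConfig(name="tropical", latitude=14.1, t_mean=27.0,
                      t_amplitude=1.8, diurnal_range=8.5, clearness_mean=0.52,
                      clearness_sd=0.12, rh_mean=0.80, wind_mean=2.0,
                      phenology=PhenologyParams(m_v=70, m_r=28, start_day=10),
                      t_phase_doy=135)


def subtropical_site() -> SiteConfig:
    """Nanjing-like archetype (single-cropping rice, emergence day 145)."""
    return SiteConfig(name="subtropical", latitude=32.9, t_mean=16.0,
                      t_amplitude=11.5, diurnal_range=8.0, clearness_mean=0.46,
                      clearness_sd=0.13, rh_mean=0.75, wind_mean=2.5,
                      phenology=PhenologyParams(m_v=85, m_r=32, start_day=145),
                      t_phase_doy=205)


def temperate_site() -> SiteConfig:
    """Shizukuishi-like archetype (emergence day 125)."""
    return SiteConfig(name="temperate", latitude=39.7, t_mean=10.5,
                      t_amplitude=12.5, diurnal_range=9.0, clearness_mean=0.45,
                      clearness_sd=0.13, rh_mean=0.75, wind_mean=2.5,
                      phenology=PhenologyParams(m_v=48, m_r=22, start_day=125),
                      t_phase_doy=210)


DEFAULT_SITES = {"tropical": tropical_site, "subtropical": subtropical_site,
                 "temperate": temperate_site}


# ---------------------------------------------------------------------------
# solar geometry
# ---------------------------------------------------------------------------

def solar_declination(doy: int | float) -> float:
    """Solar declination (radians)."""
    return -0.409 * math.cos(2.0 * math.pi * (doy + 10.0) / 365.0)


def daylength_and_radiation(latitude: float, doy: int | float) -> tuple[float, float]:
    """Daylength (h) and extraterrestrial daily radiation (MJ m-2 d-1).

    Standard declination geometry; polar day/night clamped.
    """
    lat = math.radians(latitude)
    dec = solar_declination(doy)
    cos_ws = -math.tan(lat) * math.tan(dec)
    cos_ws = min(1.0, max(-1.0, cos_ws))
    ws = math.acos(cos_ws)
    daylength = 24.0 * ws / math.pi
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    ra = (24.0 * 3600.0 / math.pi * SOLAR_CONSTANT * dr
          * (ws * math.sin(lat) * math.sin(dec)
             + math.cos(lat) * math.cos(dec) * math.sin(ws))) / 1.0e6
    return daylength, max(ra, 0.0)


def sin_elevation(latitude: float, doy: int | float, solar_hour: float) -> float:
    """Sine of solar elevation at local solar time (h, 12 = solar noon)."""
    lat = math.radians(latitude)
    dec = solar_declination(doy)
    hour_angle = math.pi * (solar_hour - 12.0) / 12.0
    return (math.sin(lat) * math.sin(dec)
            + math.cos(lat) * math.cos(dec) * math.cos(hour_angle))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

WEATHER_COLUMNS = ["year", "doy", "radiation_MJ", "tmax_C", "tmin_C",
                   "vap_kPa", "wind_ms"]

AR1_COEF = 0.6           # day-to-day persistence of temperature anomalies
T_ANOM_SD = 1.6          # degC, innovation scale of the anomaly process


def generate_weather(site: SiteConfig, n_years: int, seed: int) -> pd.DataFrame:
    """Seeded synthetic daily weather series (365-day years).

    Columns: year, doy, radiation_MJ, tmax_C, tmin_C, vap_kPa, wind_ms.
    Deterministic for a given (site, n_years, seed).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    ndays = 365 * n_years
    doy = np.tile(np.arange(1, 366), n_years)
    year = np.repeat(np.arange(1, n_years + 1), 365)

    season = np.cos(2.0 * np.pi * (doy - site.t_phase_doy) / 365.0)
    t_clim = site.t_mean + site.t_amplitude * season

    # AR(1) anomalies shared by tmax/tmin (whole-day warm or cool spells)
    innov = rng.normal(0.0, T_ANOM_SD, ndays)
    anom = np.empty(ndays)
    acc = 0.0
    for i in range(ndays):
        acc = AR1_COEF * acc + innov[i]
        anom[i] = acc
    t_day = t_clim + anom

    half_range = 0.5 * site.diurnal_range * (1.0 + 0.1 * rng.normal(0.0, 1.0, ndays))
    half_range = np.clip(half_range, 0.2 * site.diurnal_range, site.diurnal_range)
    tmax = t_day + half_range
    tmin = t_day - half_range

    clear = rng.normal(site.clearness_mean, site.clearness_sd, ndays)
    clear = np.clip(clear, 0.05, 0.75)
    ra = np.array([daylength_and_radiation(site.latitude, d)[1] for d in range(1, 366)])
    radiation = clear * np.tile(ra, n_years)

    es_tmin = np.array([saturated_vp(t) for t in tmin])
    es_mean = np.array([0.5 * (saturated_vp(a) + saturated_vp(b))
                        for a, b in zip(tmax, tmin)])
    vap = np.minimum(site.rh_mean * es_mean, es_tmin * 1.02)
    vap = np.maximum(vap, 0.05)

    wind = np.clip(rng.normal(site.wind_mean, 0.5, ndays), 0.3, None)

    return pd.DataFrame({"year": year, "doy": doy, "radiation_MJ": radiation,
                         "tmax_C": tmax, "tmin_C": tmin, "vap_kPa": vap,
                         "wind_ms": wind})


def apply_climate_2050(series: pd.DataFrame,
                       co2_baseline: float = CO2_PRESENT) -> tuple[pd.DataFrame, float]:
    """Mid-century transform: +2.0 degC on tmax and tmin, CO2 to
    550 umol mol-1, vapour pressure rescaled so relative humidity is
    preserved; radiation and wind untouched."""
    out = series.copy()
    es_old = 0.5 * (out["tmax_C"].map(saturated_vp) + out["tmin_C"].map(saturated_vp))
    out["tmax_C"] = out["tmax_C"] + WARMING_2050
    out["tmin_C"] = out["tmin_C"] + WARMING_2050
    es_new = 0.5 * (out["tmax_C"].map(saturated_vp) + out["tmin_C"].map(saturated_vp))
    out["vap_kPa"] = out["vap_kPa"] * (es_new / es_old)
    return out, CO2_2050


def write_weather_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, columns=WEATHER_COLUMNS)


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return df
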