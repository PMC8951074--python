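"""Daily weather records and derived atmospheric quantities.

Implements the meteorological primitives of the model: saturation vapour
pressure (Tetens form), daytime vapour pressure deficit from max/min
temperature and humidity, FAO-56 Penman-Monteith grass reference
evapotranspiration, and thermal time (growing degree days).

Units follow agro-meteorological convention: temperatures in degC, vapour
pressures in kPa internally with VPD reported in Pa, radiation in
MJ m-2 d-1, wind in m s-1, water fluxes in mm d-1, thermal time in degC d.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "WeatherDay",
    "SiteInfo",
    "DerivedWeather",
    "saturation_vapour_pressure",
    "daily_vpd",
    "reference_eto",
    "daily_gdd",
    "cumulative_gdd",
    "load_weather_csv",
    "weather_to_frame",
]

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 d-1 (FAO-56).
STEFAN_BOLTZMANN = 4.903e-9


@dataclass(frozen=True)
class WeatherDay:
    """One day's meteorological record from an automatic weather station.

    Attributes
    ----------
    date : datetime.date
    t_max, t_min : float
        Daily maximum / minimum air temperature, degC.
    rh_max, rh_min : float
        Daily maximum / minimum relative humidity, %.
    solar_rad : float
        Incoming (global) solar radiation, MJ m-2 d-1.
    wind : float
        Mean wind speed, m s-1 (height given by :class:`SiteInfo`).
    rain : float
        Precipitation, mm.
    """

    date: _dt.date
    t_max: float
    t_min: float
    rh_max: float
    rh_min: float
    solar_rad: float
    wind: float
    rain: float

    def __post_init__(self) -> None:
        vals = (self.t_max, self.t_min, self.rh_max, self.rh_min,
                self.solar_rad, self.wind, self.rain)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite weather value on {self.date}")
        if self.t_max < self.t_min:
            raise InvalidInputError(
                f"t_max < t_min on {self.date}: {self.t_max} < {self.t_min}")
        if not (0.0 <= self.rh_min <= self.rh_max <= 100.0):
            raise InvalidInputError(
                f"humidity out of order/range on {self.date}: "
                f"rh_min={self.rh_min}, rh_max={self.rh_max}")
        if self.solar_rad < 0:
            raise InvalidInputError(f"negative solar radiation on {self.date}")
        if self.rain < 0:
            raise InvalidInputError(f"negative rainfall on {self.date}")
        if self.wind < 0:
            raise InvalidInputError(f"negative wind speed on {self.date}")


@dataclass(frozen=True)
class SiteInfo:
    """Location of the weather station / field site.

    Defaults correspond to the Hatfield experimental farm near Pretoria
    (25 deg 45' S, 28 deg 16' E, 1327 m a.s.l.) with a standard 2 m
    anemometer.
    """

    latitude: float = -25.75
    altitude: float = 1327.0
    anemometer_height: float = 2.0

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90:
            raise InvalidConfigError(f"latitude out of range: {self.latitude}")
        if self.altitude < -430:
            raise InvalidConfigError(f"altitude below Dead Sea: {self.altitude}")
        if self.anemometer_height <= 0:
            raise InvalidConfigError("anemometer height must be positive")


@dataclass(frozen=True)
class DerivedWeather:
    """Per-day derived quantities used by the crop and soil modules."""

    eto: float      # grass reference evapotranspiration, mm d-1
    vpd: float      # vapour pressure deficit, Pa
    gdd_inc: float  # thermal time increment, degC d

    def __post_init__(self) -> None:
        if self.eto < 0 or self.vpd < 0 or self.gdd_inc < 0:
            raise InvalidInputError("derived weather quantities must be >= 0")


def saturation_vapour_pressure(ta: float) -> float:
    """Saturation vapour pressure at air temperature ``ta`` (degC), in kPa.

    Tetens form: ``es = 0.611 * exp(17.27 * ta / (ta + 237.3))``.
    Strictly increasing in ``ta``.
    """
    if not math.isfinite(ta):
        raise InvalidInputError("air temperature must be finite")
    if ta <= -40.0:
        raise InvalidInputError(f"air temperature out of validity range: {ta}")
    return 0.611 * math.exp(17.27 * ta / (ta + 237.3))


def daily_vpd(day: WeatherDay) -> float:
    """Daily vapour pressure deficit in **Pa**.

    Mean saturation vapour pressure is the arithmetic mean of es at the
    daily temperature extremes; actual vapour pressure combines each
    extreme with the humidity measured at the opposite end of the diurnal
    cycle (RHmax with Tmin, RHmin with Tmax). The result is clamped at
    zero: saturated air exerts no drying force.
    """
    es_tmax = saturation_vapour_pressure(day.t_max)
    es_tmin = saturation_vapour_pressure(day.t_min)
    es_mean = (es_tmax + es_tmin) / 2.0
    ea = (es_tmin * day.rh_max / 100.0 + es_tmax * day.rh_min / 100.0) / 2.0
    return max(0.0, es_mean - ea) * 1000.0


def _fao56_svp(ta: float) -> float:
    # FAO-56 uses 0.6108; the Tetens constant above (0.611) is reserved for
    # the VPD pathway. Both agree to <0.05%.
    return 0.6108 * math.exp(17.27 * ta / (ta + 237.3))


def extraterrestrial_radiation(latitude_deg: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra, MJ m-2 d-1 (FAO-56)."""
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    x = min(1.0, max(-1.0, x))  # polar day/night guard
    ws = math.acos(x)
    ra = (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))
    return ra


def wind_at_2m(uz: float, height: float) -> float:
    """Adjust wind speed measured at ``height`` m to the standard 2 m."""
    if height == 2.0:
        return uz
    return uz * 4.87 / math.log(67.8 * height - 5.42)


def reference_eto(day: WeatherDay, site: SiteInfo = SiteInfo()) -> float:
    """FAO-56 Penman-Monteith grass reference evapotranspiration, mm d-1.

    Standard daily formulation: albedo 0.23, soil heat flux 0, psychrometric
    constant from site altitude, net longwave from the Stefan-Boltzmann law
    with humidity and cloudiness corrections (relative shortwave Rs/Rso
    clipped to [0.3, 1.0]). The result is clamped at >= 0.
    """
    doy = day.date.timetuple().tm_yday
    ra = extraterrestrial_radiation(site.latitude, doy)
    if ra <= 0:
        raise InvalidInputError(
            f"no extraterrestrial radiation for lat={site.latitude}, doy={doy}")

    t_mean = (day.t_max + day.t_min) / 2.0
    svp = _fao56_svp(t_mean)
    delta = 4098.0 * svp / (t_mean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * site.altitude) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    es = (_fao56_svp(day.t_max) + _fao56_svp(day.t_min)) / 2.0
    ea = (_fao56_svp(day.t_min) * day.rh_max / 100.0
          + _fao56_svp(day.t_max) * day.rh_min / 100.0) / 2.0

    rso = (0.75 + 2e-5 * site.altitude) * ra
    rel_sw = min(1.0, max(0.3, day.solar_rad / rso)) if rso > 0 else 1.0
    rns = (1.0 - 0.23) * day.solar_rad
    rnl = (STEFAN_BOLTZMANN
           * ((day.t_max + 273.16) ** 4 + (day.t_min + 273.16) ** 4) / 2.0
           * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
           * (1.35 * rel_sw - 0.35))
    rn = rns - rnl

    u2 = wind_at_2m(day.wind, site.anemometer_height)
    num = (0.408 * delta * rn
           + gamma * (900.0 / (t_mean + 273.0)) * u2 * (es - ea))
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(0.0, num / den)


def daily_gdd(t_max: float, t_min: float, t_base: float,
              t_cutoff: float = 45.0) -> float:
    """Thermal-time increment for one day, degC d.

    The daily mean temperature is capped at ``t_cutoff`` before subtracting
    the base temperature; a mean at or below base contributes zero.
    """
    if t_cutoff <= t_base:
        raise InvalidConfigError(
            f"t_cutoff ({t_cutoff}) must exceed t_base ({t_base})")
    if t_max < t_min:
        raise InvalidInputError(f"t_max < t_min: {t_max} < {t_min}")
    mean = (t_max + t_min) / 2.0
    if mean <= t_base:
        return 0.0
    return min(mean, t_cutoff) - t_base


def cumulative_gdd(days: Sequence[WeatherDay], t_base: float,
                   start_date: _dt.date | None = None,
                   t_cutoff: float = 45.0) -> np.ndarray:
    """Running thermal-time sum from ``start_date`` to the series end.

    The series must be contiguous in date; element ``i`` of the result is
    the sum of daily increments over days ``start..start+i``. Empty range
    returns an empty array.
    """
    days = list(days)
    for a, b in zip(days, days[1:]):
        if (b.date - a.date).days != 1:
            raise InvalidInputError(
                f"weather series has a gap between {a.date} and {b.date}")
    if start_date is None:
        selected = days
    else:
        if days and not (days[0].date <= start_date <= days[-1].date):
            raise InvalidInputError(
                f"start_date {start_date} outside weather coverage")
        selected = [d for d in days if d.date >= start_date]
    incs = [daily_gdd(d.t_max, d.t_min, t_base, t_cutoff) for d in selected]
    return np.cumsum(incs) if incs else np.array([])


_WEATHER_COLUMNS = ["date", "tmax", "tmin", "rhmax", "rhmin", "srad", "wind", "rain"]


def load_weather_csv(path) -> list[WeatherDay]:
    """Read a daily weather CSV (``date,tmax,tmin,rhmax,rhmin,srad,wind,rain``)."""
    frame = pd.read_csv(path)
    missing = [c for c in _WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"weather CSV missing columns: {missing}")
    days = []
    for row in frame.itertuples(index=False):
        days.append(WeatherDay(
            date=pd.Timestamp(row.date).date(),
            t_max=float(row.tmax), t_min=float(row.tmin),
            rh_max=float(row.rhmax), rh_min=float(row.rhmin),
            solar_rad=float(row.srad), wind=float(row.wind),
            rain=float(row.rain)))
    return days


def weather_to_frame(days: Iterable[WeatherDay]) -> pd.DataFrame:
    """Represent a weather series as a DataFrame with the canonical columns."""
    return pd.DataFrame(
        [(d.date.isoformat(), d.t_max, d.t_min, d.rh_max, d.rh_min,
          d.solar_rad, d.wind, d.rain) for d in days],
        columns=_WEATHER_COLUMNS)
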