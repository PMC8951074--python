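"""Synthetic weather seasons and growth-analysis trials with known truth.

The weather generator emulates a semi-arid summer growing season of the
kind the model was parameterised under: daily mean temperatures sliding
from mid-20s to high-teens degC across ~130 days, vapour pressure
deficits averaging around 0.8 kPa, clear-sky radiation near
28 MJ m-2 d-1 broken by cloudy days, and episodic convective rain whose
season total is conditioned into a realistic 350-600 mm band. An optional
~208 mm three-day storm can be injected to mimic a late-season extreme
event. The trial generator runs the forward crop model under ample
irrigation, samples the state fortnightly, and perturbs the observations
with multiplicative lognormal noise -- destructive-harvest errors scale
with the quantity measured -- so the derivation pipeline can be tested
against known true parameters.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .canopy import fractional_interception
from .crop import CropParameters, Management, SeasonResult, simulate_season
from .derive import GrowthObservation
from .errors import InvalidConfigError, SimulationError
from .weather import WeatherDay

__all__ = [
    "ClimateSpec",
    "TrialSpec",
    "GrowthTrial",
    "FixtureTables",
    "generate_weather",
    "generate_growth_trial",
    "sample_observations",
    "perturb_observations",
    "load_fixture_tables",
]

#: Default sowing date matching the December planting of the source season.
DEFAULT_START_DATE = _dt.date(2017, 12, 14)


@dataclass(frozen=True)
class ClimateSpec:
    """Stochastic season recipe; identical seeds give identical series."""

    season_length: int = 130
    t_mean_range: tuple[float, float] = (18.0, 26.0)
    diurnal_range: float = 12.0
    rh_range: tuple[float, float] = (50.0, 93.0)
    srad_clear: float = 28.0
    cloud_prob: float = 0.35
    rain_prob: float = 0.28
    rain_shape: float = 0.8
    season_rain_range: tuple[float, float] = (350.0, 600.0)
    big_event_day: int | None = None
    big_event_mm: float = 208.0
    start_date: _dt.date = DEFAULT_START_DATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season_length < 1:
            raise InvalidConfigError("season_length must be >= 1")
        for name in ("cloud_prob", "rain_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        for name in ("t_mean_range", "rh_range", "season_rain_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidConfigError(f"{name} bounds out of order")
        if self.rain_shape <= 0 or self.srad_clear <= 0:
            raise InvalidConfigError("rain_shape and srad_clear must be positive")


def generate_weather(spec: ClimateSpec) -> list[WeatherDay]:
    """Generate one season of daily weather from the spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.season_length
    lo, hi = spec.t_mean_range

    trend = (np.full(n, hi) if n == 1
             else hi - (hi - lo) * np.arange(n) / (n - 1))
    t_mean = np.clip(trend + rng.normal(0.0, 1.2, n), lo, hi)

    cloudy = rng.random(n) < spec.cloud_prob
    raining = rng.random(n) < spec.rain_prob
    cloudy |= raining  # rain only falls from clouds

    rain = np.zeros(n)
    if spec.rain_prob > 0:
        idx = np.flatnonzero(raining)
        if idx.size == 0:  # degenerate draw: force a single rain day
            idx = np.array([rng.integers(n)])
        total = rng.uniform(*spec.season_rain_range)
        weights = rng.gamma(spec.rain_shape, 1.0, idx.size)
        weights = weights / weights.sum() if weights.sum() > 0 else \
            np.full(idx.size, 1.0 / idx.size)
        rain[idx] = total * weights
    if spec.big_event_day is not None:
        for offset, share in enumerate((0.25, 0.5, 0.25)):
            day = spec.big_event_day + offset
            if 0 <= day < n:
                rain[day] += spec.big_event_mm * share

    diurnal = spec.diurnal_range * np.where(cloudy, 0.7, 1.0)
    t_max = t_mean + diurnal / 2.0
    t_min = t_mean - diurnal / 2.0

    rh_lo, rh_hi = spec.rh_range
    rh_max = np.clip(rh_hi - rng.uniform(0.0, 5.0, n)
                     + np.where(raining, 5.0, 0.0), 0.0, 100.0)
    rh_min = np.clip(rh_lo + rng.uniform(0.0, 10.0, n)
                     + np.where(cloudy, 10.0, 0.0), 0.0, 100.0)
    rh_min = np.minimum(rh_min, rh_max)

    srad = spec.srad_clear * np.where(cloudy,
                                      rng.uniform(0.30, 0.70, n),
                                      rng.uniform(0.75, 1.00, n))
    wind = rng.gamma(4.0, 0.5, n)  # mean 2 m s-1, light-to-moderate

    return [WeatherDay(date=spec.start_date + _dt.timedelta(days=i),
                       t_max=float(t_max[i]), t_min=float(t_min[i]),
                       rh_max=float(rh_max[i]), rh_min=float(rh_min[i]),
                       solar_rad=float(srad[i]), wind=float(wind[i]),
                       rain=float(rain[i]))
            for i in range(n)]


def _default_trial_truth() -> CropParameters:
    # Growth-analysis trials emulate AGDM-based parameter definitions:
    # RUE, DWR and p are derived from above-ground mass with roots
    # excluded, so the trial forward model allocates all assimilate to
    # the shoot.
    from .config import load_crop_parameters

    return dataclasses.replace(load_crop_parameters("kantana"),
                               root_fraction_initial=0.0)


@dataclass(frozen=True)
class TrialSpec:
    """Recipe for a synthetic growth-analysis trial."""

    true_params: CropParameters | None = None
    sampling_interval: int = 14
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval < 1:
            raise InvalidConfigError("sampling_interval must be >= 1")
        if self.noise_cv < 0:
            raise InvalidConfigError("noise_cv must be >= 0")

    def resolved_params(self) -> CropParameters:
        return self.true_params if self.true_params is not None \
            else _default_trial_truth()


@dataclass(frozen=True)
class GrowthTrial:
    """Synthetic trial: noisy observations plus the generating truth."""

    observations: list[GrowthObservation]
    truth: CropParameters
    result: SeasonResult


def sample_observations(result: SeasonResult, weather: Sequence[WeatherDay],
                        sampling_interval: int) -> list[GrowthObservation]:
    """Noise-free destructive-harvest samples from a simulated season.

    Sampling runs every ``sampling_interval`` days after sowing; only days
    with a live canopy are recorded. ``fi_par`` is the Beer-Bouguer
    interception at the variety's PAR extinction coefficient; the
    cumulative FI*Rs uses the total-solar interception actually driving
    growth.
    """
    params = result.params
    cum = 0.0
    cum_by_index = []
    for rec in result.days:
        cum += rec.fi_rad * weather[rec.day_index].solar_rad
        cum_by_index.append(cum)
    obs = []
    for rec in result.days:
        if rec.day_index % sampling_interval != 0 or rec.day_index == 0:
            continue
        s = rec.state
        if s.lai <= 0:
            continue
        obs.append(GrowthObservation(
            date=rec.date, lai=s.lai, leaf_area=s.lai, ldm=s.ldm,
            sdm=s.sdm, agdm=s.agdm, hdm=s.hdm,
            fi_par=fractional_interception(params.k_par, s.lai),
            cum_fi_rs=cum_by_index[rec.day_index]))
    return obs


def perturb_observations(observations: Sequence[GrowthObservation],
                         noise_cv: float,
                         rng: np.random.Generator) -> list[GrowthObservation]:
    """Apply measurement noise to noise-free samples.

    Masses and areas get independent multiplicative lognormal factors with
    coefficient of variation ``noise_cv`` (unit mean); the bounded
    ``fi_par`` is perturbed on the logit scale and clamped to (0, 1).
    ``leaf_area`` carries the same factor as ``lai`` (one area measurement
    reported two ways), so cum_fi_rs stays untouched as a weather-derived
    covariate.
    """
    if noise_cv == 0:
        return list(observations)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))

    def factor() -> float:
        return float(rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma))

    noisy = []
    for o in observations:
        lai = o.lai * factor()
        ldm = o.ldm * factor()
        sdm = o.sdm * factor()
        agdm = o.agdm * factor()
        hdm = o.hdm * factor() if o.hdm > 0 else 0.0
        logit = math.log(o.fi_par / (1.0 - o.fi_par)) \
            + float(rng.normal(0.0, noise_cv))
        fi = 1.0 / (1.0 + math.exp(-logit))
        fi = min(max(fi, 1e-6), 1.0 - 1e-6)
        noisy.append(GrowthObservation(
            date=o.date, lai=lai, leaf_area=lai, ldm=ldm, sdm=sdm,
            agdm=agdm, hdm=hdm, fi_par=fi, cum_fi_rs=o.cum_fi_rs))
    return noisy


def generate_growth_trial(spec: TrialSpec,
                          weather: Sequence[WeatherDay]) -> GrowthTrial:
    """Simulate a well-watered trial and emit (noisy) observations + truth.

    The season runs under daily refill-to-field-capacity ("ample
    irrigation") so growth stays radiation-limited, as in the well-watered
    calibration plots the pipeline was designed for.
    """
    truth = spec.resolved_params()
    result = simulate_season(truth, weather,
                             management=Management(mode="daily_refill"))
    if result.status == "ended_before_emergence":
        raise SimulationError("weather ended before crop emergence")
    clean = sample_observations(result, list(weather), spec.sampling_interval)
    if len(clean) < 3:
        raise SimulationError(
            f"trial produced only {len(clean)} usable samplings")
    rng = np.random.default_rng(spec.seed)
    return GrowthTrial(observations=perturb_observations(clean, spec.noise_cv, rng),
                       truth=truth, result=result)


class FixtureTables(NamedTuple):
    """The packaged observed tables: weekly balance, seasonal balance, parameters."""

    weekly_balance: pd.DataFrame
    seasonal_balance: pd.DataFrame
    parameters: pd.DataFrame


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("milletswb.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fixture_tables() -> FixtureTables:
    """Load the observed water-balance and parameter tables shipped as data.

    ``weekly_balance``: weekly P, I, ET, D, R, root-zone storage at the
    start (Qi) and end (Qo) of each measurement period, and the printed
    storage-change column dS (which carries the opposite sign to Qo - Qi,
    as printed in the source). ``seasonal_balance``: season totals plus
    seasonal ETo and mean VPD (kPa). ``parameters``: the per-variety
    growth parameters.
    """
    return FixtureTables(
        weekly_balance=_read_packaged("table1_weekly_balance.csv"),
        seasonal_balance=_read_packaged("table2_seasonal.csv"),
        parameters=_read_packaged("table3_parameters.csv"))
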