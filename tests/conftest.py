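import dataclasses
import datetime as dt

import pytest

from milletswb import (ClimateSpec, Management, WeatherDay,
                       generate_weather, load_crop_parameters)


def make_day(date=dt.date(2018, 1, 15), t_max=30.0, t_min=18.0,
             rh_max=85.0, rh_min=40.0, solar_rad=25.0, wind=2.0,
             rain=0.0) -> WeatherDay:
    return WeatherDay(date=date, t_max=t_max, t_min=t_min, rh_max=rh_max,
                      rh_min=rh_min, solar_rad=solar_rad, wind=wind,
                      rain=rain)


def constant_weather(n, t_max, t_min, rain=0.0,
                     start=dt.date(2017, 12, 14), **kwargs):
    return [make_day(date=start + dt.timedelta(days=i), t_max=t_max,
                     t_min=t_min, rain=rain, **kwargs) for i in range(n)]


@pytest.fixture(scope="session")
def kantana():
    return load_crop_parameters("kantana")


@pytest.fixture(scope="session")
def kangara():
    return load_crop_parameters("kangara")


@pytest.fixture(scope="session")
def agrigreen():
    return load_crop_parameters("agrigreen")


@pytest.fixture(scope="session")
def season_weather():
    """A default-condition synthetic season, fixed seed."""
    return generate_weather(ClimateSpec(seed=7))


@pytest.fixture(scope="session")
def long_warm_weather():
    """A long season so even the late landrace reaches maturity."""
    return generate_weather(ClimateSpec(season_length=210, seed=11))


@pytest.fixture
def trial_truth(kantana):
    """Shoot-only truth used by growth-analysis trials."""
    return dataclasses.replace(kantana, root_fraction_initial=0.0)


@pytest.fixture
def ample_management():
    return Management(mode="daily_refill")
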