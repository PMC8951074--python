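"""Derive the atmospheric drivers for one mid-summer day.

Builds a single weather record for the Pretoria site and prints the three
quantities the crop model consumes: grass reference evapotranspiration
(the day's evaporative demand), vapour pressure deficit (the drying force
that scales water-limited growth) and the growing-degree-day increment
(thermal time that advances phenology, base 10 degC).
"""

import datetime as dt

from milletswb import SiteInfo, WeatherDay, daily_gdd, daily_vpd, reference_eto

day = WeatherDay(date=dt.date(2018, 1, 15), t_max=30.0, t_min=18.0,
                 rh_max=85.0, rh_min=40.0, solar_rad=25.0, wind=2.0, rain=0.0)
site = SiteInfo()  # Hatfield: 25.75 S, 1327 m a.s.l.

print(f"ETo      = {reference_eto(day, site):.2f} mm/day")
print(f"VPD      = {daily_vpd(day):.0f} Pa")
print(f"GDD inc. = {daily_gdd(day.t_max, day.t_min, t_base=10.0):.1f} degC d")
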