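"""Independent step-by-step FAO-56 daily reference-ET computation.

Deliberately written from the worked-example recipe (box-by-box, named
intermediates, no shared code with the package) to serve as an oracle for
the package's Penman-Monteith implementation.
"""

import math


def eto_fao56(tmax, tmin, rhmax, rhmin, rs, uz, z_wind, latitude_deg,
              altitude_m, doy):
    # Step 1: mean temperature and slope of the svp curve
    tmean = (tmax + tmin) / 2
    e0 = lambda t: 0.6108 * math.exp(17.27 * t / (t + 237.3))
    slope = 4098 * e0(tmean) / (tmean + 237.3) ** 2

    # Step 2: psychrometric constant from atmospheric pressure
    patm = 101.3 * ((293 - 0.0065 * altitude_m) / 293) ** 5.26
    gamma = 0.000665 * patm

    # Step 3: vapour pressures
    es = (e0(tmax) + e0(tmin)) / 2
    ea = (e0(tmin) * rhmax / 100 + e0(tmax) * rhmin / 100) / 2

    # Step 4: extraterrestrial and clear-sky radiation
    gsc = 0.0820
    phi = latitude_deg * math.pi / 180
    dr = 1 + 0.033 * math.cos(2 * math.pi / 365 * doy)
    dec = 0.409 * math.sin(2 * math.pi / 365 * doy - 1.39)
    omega_s = math.acos(max(-1.0, min(1.0, -math.tan(phi) * math.tan(dec))))
    ra = (24 * 60 / math.pi) * gsc * dr * (
        omega_s * math.sin(phi) * math.sin(dec)
        + math.cos(phi) * math.cos(dec) * math.sin(omega_s))
    rso = (0.75 + 2e-5 * altitude_m) * ra

    # Step 5: net radiation (albedo 0.23; Rs/Rso clipped to [0.3, 1.0])
    rns = 0.77 * rs
    sigma = 4.903e-9
    tk4 = ((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2
    rel = rs / rso if rso > 0 else 1.0
    rel = max(0.3, min(1.0, rel))
    rnl = sigma * tk4 * (0.34 - 0.14 * math.sqrt(ea)) * (1.35 * rel - 0.35)
    rn = rns - rnl

    # Step 6: wind at 2 m
    if z_wind == 2.0:
        u2 = uz
    else:
        u2 = uz * 4.87 / math.log(67.8 * z_wind - 5.42)

    # Step 7: combination equation, soil heat flux 0 for daily steps
    numerator = 0.408 * slope * rn + gamma * 900 / (tmean + 273) * u2 * (es - ea)
    denominator = slope + gamma * (1 + 0.34 * u2)
    return max(0.0, numerator / denominator)
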