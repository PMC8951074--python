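"""Growth-analysis parameter derivation.

Reproduces the fitting pipeline that turns fortnightly destructive-harvest
observations into crop model parameters: radiation use efficiency (slope
of above-ground dry matter on cumulative intercepted radiation, forced
through the origin), the PAR extinction coefficient (through-origin slope
of the log-linearised Beer-Bouguer law), the leaf-stem partitioning
parameter p, seasonal mean specific leaf area, a lower-limit dry-matter
water ratio, stage thermal-time thresholds from phenology dates, and
water use efficiency.

All forced-origin fits use the closed form ``slope = sum(xy) / sum(x^2)``
with the no-intercept coefficient of determination
``r^2 = 1 - SS_res / sum(y^2)``.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InvalidInputError
from .soil import SoilProfile
from .stats import willmott_d
from .weather import WeatherDay, cumulative_gdd

__all__ = [
    "GrowthObservation",
    "FitResult",
    "fit_rue",
    "fit_kpar",
    "fit_partition_p",
    "mean_sla",
    "dwr_lower_limit",
    "stage_gdd",
    "wue",
    "dwr_sweep",
    "derive_parameters",
    "load_trial_csv",
    "trial_to_frame",
]


@dataclass(frozen=True)
class GrowthObservation:
    """One destructive-harvest sampling event.

    Masses in kg m-2 per unit ground area, areas in m2 m-2; ``cum_fi_rs``
    is the cumulative product of fractional interception and solar
    radiation (MJ m-2) up to the sampling date.
    """

    date: _dt.date
    lai: float
    leaf_area: float
    ldm: float
    sdm: float
    agdm: float
    hdm: float
    fi_par: float
    cum_fi_rs: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fi_par <= 1.0):
            raise InvalidInputError(f"fi_par out of [0, 1]: {self.fi_par}")
        if min(self.lai, self.leaf_area, self.ldm, self.sdm, self.agdm,
               self.hdm, self.cum_fi_rs) < 0:
            raise InvalidInputError("growth observation fields must be >= 0")

    @property
    def cdm(self) -> float:
        return self.ldm + self.sdm


@dataclass(frozen=True)
class FitResult:
    """A fitted parameter with its goodness of fit."""

    estimate: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateFitError(f"fit needs >= 2 points, got {self.n}")
        if self.r_squared > 1 + 1e-12:
            raise DegenerateFitError(f"r_squared > 1: {self.r_squared}")


def through_origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of ``y = b x`` and its no-intercept r-squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise DegenerateFitError("regressor is identically zero")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    ss_res = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 if syy == 0.0 else 1.0 - ss_res / syy
    return slope, r2


def fit_rue(observations: Sequence[GrowthObservation],
            dm_at_emergence: float = 0.0) -> FitResult:
    """Radiation use efficiency, kg MJ-1.

    Through-origin slope of above-ground dry matter on cumulative
    intercepted solar radiation. ``dm_at_emergence`` (kg m-2), if given, is
    the known seed-reserve mass present at emergence, subtracted from the
    response before fitting so the forced-origin model is unbiased.
    """
    obs = [o for o in observations if o.cum_fi_rs > 0]
    if len(obs) < 3:
        raise DegenerateFitError(
            f"need >= 3 observations with positive cumulative FI*Rs, "
            f"got {len(obs)}")
    x = np.array([o.cum_fi_rs for o in obs])
    y = np.array([o.agdm - dm_at_emergence for o in obs])
    slope, r2 = through_origin_slope(x, y)
    return FitResult(estimate=slope, r_squared=r2, n=len(obs))


def fit_kpar(lai_values: Sequence[float],
             fi_par_values: Sequence[float]) -> FitResult:
    """PAR extinction coefficient from paired (LAI, FI_PAR) measurements.

    Log-linearised Beer-Bouguer law: through-origin slope of
    ``-ln(1 - FI)`` on LAI; r-squared on the linearised scale.
    """
    lai = np.asarray(lai_values, dtype=float)
    fi = np.asarray(fi_par_values, dtype=float)
    if lai.shape != fi.shape:
        raise InvalidInputError("lai and fi_par series differ in length")
    if lai.size < 3:
        raise DegenerateFitError(f"need >= 3 pairs, got {lai.size}")
    if np.any(fi >= 1.0):
        raise InvalidInputError("fi_par = 1 gives an infinite transform")
    if np.any(fi < 0) or np.any(lai < 0):
        raise InvalidInputError("lai and fi_par must be >= 0")
    y = -np.log1p(-fi)
    slope, r2 = through_origin_slope(lai, y)
    return FitResult(estimate=slope, r_squared=r2, n=int(lai.size))


def fit_partition_p(cdm_values: Sequence[float], sla: float,
                    lai_values: Sequence[float]) -> FitResult:
    """Leaf-stem partitioning parameter p, m2 kg-1.

    Through-origin slope of ``(SLA * CDM / LAI) - 1`` on CDM. Because
    LAI = SLA * LDM, the response reduces to ``CDM/LDM - 1 = p * CDM``
    under the partitioning law, so the slope recovers p.
    """
    cdm = np.asarray(cdm_values, dtype=float)
    lai = np.asarray(lai_values, dtype=float)
    if cdm.shape != lai.shape:
        raise InvalidInputError("cdm and lai series differ in length")
    if cdm.size < 3:
        raise DegenerateFitError(f"need >= 3 triples, got {cdm.size}")
    if sla <= 0:
        raise InvalidInputError(f"sla must be positive: {sla}")
    if np.any(lai <= 0):
        raise InvalidInputError("lai must be positive for the p regression")
    y = sla * cdm / lai - 1.0
    slope, r2 = through_origin_slope(cdm, y)
    return FitResult(estimate=slope, r_squared=r2, n=int(cdm.size))


def mean_sla(leaf_area_values: Sequence[float],
             ldm_values: Sequence[float]) -> float:
    """Seasonal mean specific leaf area, m2 kg-1.

    Unweighted mean of per-sampling leaf-area / leaf-dry-matter ratios;
    zero-mass samplings are skipped with a warning.
    """
    la = np.asarray(leaf_area_values, dtype=float)
    ldm = np.asarray(ldm_values, dtype=float)
    if la.shape != ldm.shape:
        raise InvalidInputError("leaf_area and ldm series differ in length")
    usable = ldm > 0
    if not np.all(usable):
        warnings.warn(f"skipping {int(np.sum(~usable))} samplings with zero "
                      "leaf dry matter", stacklevel=2)
    if not np.any(usable):
        raise DegenerateFitError("no samplings with positive leaf dry matter")
    return float(np.mean(la[usable] / ldm[usable]))


def dwr_lower_limit(agdm_at_maturity: float, seasonal_et: float,
                    seasonal_mean_vpd: float) -> float:
    """Lower-bound dry-matter water ratio, Pa.

    ``DWR >= AGDM * VPD / ET`` (ET in mm is numerically kg water m-2).
    Using ET instead of transpiration and above-ground instead of total dry
    matter both inflate the denominator / deflate the numerator, so the
    value is a lower bound on the true DWR.
    """
    if seasonal_et <= 0:
        raise InvalidInputError(f"seasonal ET must be positive: {seasonal_et}")
    if seasonal_mean_vpd <= 0:
        raise InvalidInputError(
            f"seasonal mean VPD must be positive: {seasonal_mean_vpd}")
    if agdm_at_maturity < 0:
        raise InvalidInputError("above-ground dry matter must be >= 0")
    return agdm_at_maturity * seasonal_mean_vpd / seasonal_et


def stage_gdd(phenology_dates: dict[str, _dt.date],
              weather: Sequence[WeatherDay], t_base: float,
              t_cutoff: float = 45.0) -> dict[str, float]:
    """Thermal time from sowing to each phenology date, degC d.

    ``phenology_dates`` must contain ``sowing`` plus any later events
    (``emergence``, ``flowering``, ``maturity``...), ordered in time. The
    sowing day itself contributes no thermal time (accumulation starts the
    day after sowing), so same-day sowing and emergence give 0.
    """
    if "sowing" not in phenology_dates:
        raise InvalidInputError("phenology_dates must include 'sowing'")
    sowing = phenology_dates["sowing"]
    weather = list(weather)
    if not weather:
        raise InvalidInputError("empty weather series")
    lo, hi = weather[0].date, weather[-1].date
    events = sorted((d, name) for name, d in phenology_dates.items())
    for (d1, n1), (d2, n2) in zip(events, events[1:]):
        if d1 > d2:
            raise InvalidInputError(f"phenology out of order: {n1} after {n2}")
    for name, d in phenology_dates.items():
        if not (lo <= d <= hi):
            raise InvalidInputError(
                f"{name} date {d} outside weather coverage {lo}..{hi}")
        if name != "sowing" and d < sowing:
            raise InvalidInputError(f"{name} precedes sowing")
    running = cumulative_gdd(weather, t_base, start_date=sowing,
                             t_cutoff=t_cutoff)
    out = {}
    for name, d in phenology_dates.items():
        offset = (d - sowing).days
        out[name] = 0.0 if offset <= 0 else float(running[offset - 1])
    return out


def wue(yield_dm: float, seasonal_et: float) -> float:
    """Water use efficiency, kg of dry matter per m3 of water."""
    if seasonal_et <= 0:
        raise InvalidInputError(f"seasonal ET must be positive: {seasonal_et}")
    if yield_dm < 0:
        raise InvalidInputError("yield must be >= 0")
    return yield_dm / (seasonal_et / 1000.0)


def dwr_sweep(base_params, weather, observed_dates: Sequence[_dt.date],
              observed_deficits: Sequence[float],
              dwr_values: Sequence[float],
              soil: SoilProfile | None = None,
              management=None) -> tuple[float, list[tuple[float, float]]]:
    """Scalar DWR calibration sweep.

    Re-simulates the season for each candidate DWR and scores the simulated
    root-zone deficit against observations with the Willmott index of
    agreement on the matching dates. Returns the best candidate and the
    full (dwr, D) table. This mirrors the manual upward adjustment of the
    lower-limit DWR during calibration; it is a sweep, not an optimiser.
    """
    from dataclasses import replace as _dc_replace

    from .crop import simulate_season

    if len(observed_dates) != len(observed_deficits):
        raise InvalidInputError("observed dates and deficits differ in length")
    if not dwr_values:
        raise InvalidInputError("empty DWR candidate list")
    wanted = {d: v for d, v in zip(observed_dates, observed_deficits)}
    scores = []
    for cand in dwr_values:
        params = _dc_replace(base_params, dwr=float(cand))
        result = simulate_season(params, weather, soil=soil,
                                 management=management)
        sim = {rec.date: rec.deficit_mm for rec in result.days}
        common = [d for d in wanted if d in sim]
        if len(common) < 2:
            raise InvalidInputError(
                "fewer than 2 observation dates inside the simulated season")
        obs_v = [wanted[d] for d in common]
        sim_v = [sim[d] for d in common]
        scores.append((float(cand), willmott_d(obs_v, sim_v)))
    best = max(scores, key=lambda t: t[1])[0]
    return best, scores


def derive_parameters(observations: Sequence[GrowthObservation],
                      dm_at_emergence: float = 0.0) -> dict[str, FitResult | float]:
    """Run the full derivation pipeline on one trial.

    Returns RUE, K_PAR and p as :class:`FitResult` and mean SLA as a float.
    SLA is fitted first because the p regression needs it.
    """
    sla = mean_sla([o.leaf_area for o in observations],
                   [o.ldm for o in observations])
    return {
        "rue": fit_rue(observations, dm_at_emergence=dm_at_emergence),
        "k_par": fit_kpar([o.lai for o in observations],
                          [o.fi_par for o in observations]),
        "p": fit_partition_p([o.cdm for o in observations], sla,
                             [o.lai for o in observations]),
        "sla": sla,
    }


_TRIAL_COLUMNS = ["date", "lai", "leaf_area", "ldm", "sdm", "agdm", "hdm",
                  "fi_par", "cum_fi_rs"]


def load_trial_csv(path) -> list[GrowthObservation]:
    """Read a growth-trial CSV with the canonical observation columns."""
    frame = pd.read_csv(path)
    missing = [c for c in _TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"trial CSV missing columns: {missing}")
    return [GrowthObservation(
        date=pd.Timestamp(row.date).date(), lai=float(row.lai),
        leaf_area=float(row.leaf_area), ldm=float(row.ldm),
        sdm=float(row.sdm), agdm=float(row.agdm), hdm=float(row.hdm),
        fi_par=float(row.fi_par), cum_fi_rs=float(row.cum_fi_rs))
        for row in frame.itertuples(index=False)]


def trial_to_frame(observations: Sequence[GrowthObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.date.isoformat(), o.lai, o.leaf_area, o.ldm, o.sdm, o.agdm,
          o.hdm, o.fi_par, o.cum_fi_rs) for o in observations],
        columns=_TRIAL_COLUMNS)
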