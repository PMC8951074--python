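"""Daily crop state update and the full-season simulation driver.

Phenology runs on thermal time: the crop is sown, emerges once cumulative
growing degree days pass the emergence threshold, grows vegetatively,
switches assimilate allocation to grain at the transition threshold, and
matures at the maturity threshold. Daily dry-matter production is the
minimum of a radiation-limited rate (radiation use efficiency times
intercepted solar radiation) and a transpiration-limited rate (dry-matter
water ratio times actual transpiration over vapour pressure deficit).
Shoot assimilate is re-partitioned between leaf and stem through the
leaf-stem parameter p::

    LDM = CDM / (1 + p * CDM)
    SDM = CDM - LDM

and leaf area index follows from specific leaf area, LAI = SLA * LDM.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .canopy import DEFAULT_A_N, DEFAULT_A_P, fractional_interception, kpar_to_ks
from .errors import InvalidConfigError, InvalidInputError
from .soil import (SoilProfile, WaterFluxDay, extract_evaporation,
                   extract_transpiration, infiltrate_cascade,
                   irrigation_decision, partition_et, profile_deficit,
                   stress_index)
from .weather import (DerivedWeather, SiteInfo, WeatherDay, daily_gdd,
                      daily_vpd, reference_eto)

__all__ = [
    "Stage",
    "CropParameters",
    "CropState",
    "Management",
    "DayRecord",
    "SeasonResult",
    "advance_phenology",
    "dm_increment",
    "partition_dm",
    "update_lai",
    "root_depth",
    "root_fraction",
    "simulate_season",
]

#: VPD below this floor (Pa) is treated as the floor in the
#: transpiration-limited rate, preventing blow-up on near-saturated days.
VPD_FLOOR_PA = 100.0

#: Root depth of the germinating seedling, m.
SEEDLING_ROOT_DEPTH = 0.05


class Stage(enum.Enum):
    """Phenological stage, ordered and irreversible.

    ``EMERGED`` is reported on the update in which cumulative thermal time
    crosses the emergence threshold; subsequent vegetative-phase updates
    report ``VEGETATIVE`` (identical partitioning behaviour).
    """

    PRESOW = "presow"
    SOWN = "sown"
    EMERGED = "emerged"
    VEGETATIVE = "vegetative"
    REPRODUCTIVE = "reproductive"
    MATURE = "mature"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]

    @property
    def canopy_active(self) -> bool:
        return _STAGE_ORDER[Stage.EMERGED] <= self.order < _STAGE_ORDER[Stage.MATURE]


_STAGE_ORDER = {Stage.PRESOW: 0, Stage.SOWN: 1, Stage.EMERGED: 2,
                Stage.VEGETATIVE: 2, Stage.REPRODUCTIVE: 3, Stage.MATURE: 4}


@dataclass(frozen=True)
class CropParameters:
    """Variety-specific growth constants.

    Units: rue kg MJ-1; dwr Pa; sla and p m2 kg-1; depths/heights m;
    t_max_rate mm d-1; temperatures degC; thermal-time thresholds degC d;
    dm_at_emergence kg m-2; stress_threshold and root_fraction_initial are
    fractions. ``k_s`` is always derived from ``k_par`` and the leaf
    absorptances.
    """

    name: str
    rue: float
    dwr: float
    k_par: float
    sla: float
    p: float
    gdd_emerge: float
    gdd_transition: float
    gdd_flower: float
    gdd_maturity: float
    a_p: float = DEFAULT_A_P
    a_n: float = DEFAULT_A_N
    rd_max: float = 1.00
    h_max: float = 3.0
    t_max_rate: float = 9.0
    t_base: float = 10.0
    t_opt: float = 33.0       # stored for completeness, unused in thermal time
    t_cutoff: float = 45.0
    dm_at_emergence: float = 0.0019
    stress_threshold: float = 0.30
    root_fraction_initial: float = 0.25
    stress_gdd_modifier: float = 0.0  # stress slow-down of thermal time, off
    k_s: float = field(init=False)

    def __post_init__(self) -> None:
        positive = ("rue", "dwr", "k_par", "sla", "rd_max", "h_max",
                    "t_max_rate", "gdd_emerge", "gdd_transition",
                    "gdd_flower", "gdd_maturity", "dm_at_emergence")
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.p < 0:
            raise InvalidConfigError("p must be >= 0")
        if not (self.gdd_emerge < self.gdd_transition
                < self.gdd_flower < self.gdd_maturity):
            raise InvalidConfigError(
                "thermal-time thresholds must be ordered "
                "emerge < transition < flower < maturity")
        if not (self.t_base < self.t_opt < self.t_cutoff):
            raise InvalidConfigError(
                "cardinal temperatures must be ordered base < opt < cutoff")
        if not (0 < self.stress_threshold < 1):
            raise InvalidConfigError("stress_threshold must be in (0, 1)")
        if not (0 <= self.root_fraction_initial < 1):
            raise InvalidConfigError("root_fraction_initial must be in [0, 1)")
        object.__setattr__(
            self, "k_s", kpar_to_ks(self.k_par, self.a_p, self.a_n))


@dataclass
class CropState:
    """Mutable daily crop state.

    Dry-matter pools (kg m-2): ldm leaf, sdm stem, hdm harvestable (grain),
    rdm root. ``cdm`` (canopy) = ldm + sdm; ``agdm`` (above-ground)
    = cdm + hdm. ``lai = sla * ldm`` is maintained after every partition
    step.
    """

    gdd_cum: float = 0.0
    stage: Stage = Stage.SOWN
    ldm: float = 0.0
    sdm: float = 0.0
    hdm: float = 0.0
    rdm: float = 0.0
    lai: float = 0.0
    root_depth: float = SEEDLING_ROOT_DEPTH
    si_today: float = 0.0

    @property
    def cdm(self) -> float:
        return self.ldm + self.sdm

    @property
    def agdm(self) -> float:
        return self.cdm + self.hdm

    @property
    def total_dm(self) -> float:
        return self.agdm + self.rdm


@dataclass(frozen=True)
class Management:
    """Irrigation management: refill mode and schedule anchor."""

    mode: str = "weekly_refill"
    first_irrigation_day: int | None = None


def _stage_from_gdd(gdd: float, params: CropParameters) -> Stage:
    if gdd < params.gdd_emerge:
        return Stage.SOWN
    if gdd < params.gdd_transition:
        return Stage.VEGETATIVE
    if gdd < params.gdd_maturity:
        return Stage.REPRODUCTIVE
    return Stage.MATURE


def advance_phenology(state: CropState, gdd_inc: float, si: float,
                      params: CropParameters) -> Stage:
    """Accumulate thermal time and advance the phenological stage.

    Thermal-time accumulation can optionally be slowed by water stress
    (``stress_gdd_modifier``, shipped as 0 = off). Transitions are
    irreversible; crossing the emergence threshold reports
    :attr:`Stage.EMERGED` for that update.
    """
    if gdd_inc < 0:
        raise InvalidInputError(f"negative GDD increment: {gdd_inc}")
    if not (0 <= si <= 1):
        raise InvalidInputError(f"stress index out of [0, 1]: {si}")
    was_emerged = state.gdd_cum >= params.gdd_emerge
    state.gdd_cum += gdd_inc * (1.0 - si * params.stress_gdd_modifier)
    new_stage = _stage_from_gdd(state.gdd_cum, params)
    if new_stage is Stage.VEGETATIVE and not was_emerged:
        new_stage = Stage.EMERGED
    if new_stage.order > state.stage.order or (
            new_stage is Stage.VEGETATIVE and state.stage is Stage.EMERGED):
        state.stage = new_stage
    return state.stage


def dm_increment(t_act: float, vpd: float, fi_rad: float, solar_rad: float,
                 params: CropParameters,
                 vpd_floor: float = VPD_FLOOR_PA) -> float:
    """Daily dry-matter production (kg m-2 d-1), the stricter of two limits.

    Radiation-limited: ``RUE * FI_RAD * Rs``. Transpiration-limited (daily
    form of the VPD-normalised water-productivity relation):
    ``DWR * T_act / max(VPD, floor)``.
    """
    if min(t_act, vpd, fi_rad, solar_rad) < 0:
        raise InvalidInputError("dm_increment inputs must be >= 0")
    dm_rad = params.rue * fi_rad * solar_rad
    dm_water = params.dwr * t_act / max(vpd, vpd_floor)
    return min(dm_rad, dm_water)


def root_fraction(gdd_cum: float, params: CropParameters) -> float:
    """Assimilate fraction routed to roots, declining linearly to 0 at flowering."""
    if gdd_cum >= params.gdd_flower:
        return 0.0
    if gdd_cum <= params.gdd_emerge:
        return params.root_fraction_initial
    span = params.gdd_flower - params.gdd_emerge
    return params.root_fraction_initial * (params.gdd_flower - gdd_cum) / span


def partition_dm(state: CropState, dm_inc: float, stage: Stage,
                 params: CropParameters) -> CropState:
    """Distribute a day's dry-matter increment among the organ pools.

    A root share (declining with development) goes below ground. During the
    vegetative phase the shoot share enters the canopy pool, which is
    re-split into leaf and stem; during the reproductive phase it goes to
    grain. Mass is conserved exactly.
    """
    if dm_inc < 0:
        raise InvalidInputError(f"negative dry-matter increment: {dm_inc}")
    fr = root_fraction(state.gdd_cum, params)
    root_gain = dm_inc * fr
    shoot_gain = dm_inc - root_gain
    state.rdm += root_gain
    if stage in (Stage.EMERGED, Stage.VEGETATIVE):
        cdm = state.cdm + shoot_gain
        state.ldm = cdm / (1.0 + params.p * cdm)
        state.sdm = cdm - state.ldm
    elif stage is Stage.REPRODUCTIVE:
        state.hdm += shoot_gain
    else:
        # no active canopy: return the shoot share to keep mass conserved
        state.rdm += shoot_gain
    state.lai = update_lai(state.ldm, params.sla)
    return state


def update_lai(ldm: float, sla: float) -> float:
    """Leaf area index from leaf dry matter: ``LAI = SLA * LDM``."""
    if ldm < 0:
        raise InvalidInputError(f"negative leaf dry matter: {ldm}")
    if sla <= 0:
        raise InvalidInputError(f"specific leaf area must be positive: {sla}")
    return sla * ldm


def root_depth(gdd_cum: float, params: CropParameters) -> float:
    """Rooting depth (m): linear from 0.05 m at emergence to rd_max at flowering."""
    if gdd_cum < 0:
        raise InvalidInputError(f"negative cumulative GDD: {gdd_cum}")
    if gdd_cum <= params.gdd_emerge:
        return SEEDLING_ROOT_DEPTH
    if gdd_cum >= params.gdd_flower:
        return params.rd_max
    frac = (gdd_cum - params.gdd_emerge) / (params.gdd_flower - params.gdd_emerge)
    return SEEDLING_ROOT_DEPTH + (params.rd_max - SEEDLING_ROOT_DEPTH) * frac


@dataclass(frozen=True)
class DayRecord:
    """One simulated day: weather drivers, water fluxes and crop state."""

    date: _dt.date
    day_index: int
    derived: DerivedWeather
    flux: WaterFluxDay
    state: CropState
    fi_rad: float
    deficit_mm: float
    dm_inc: float


@dataclass
class SeasonResult:
    """Full-season trace plus completion status.

    ``status`` is ``"mature"`` when the crop reached the maturity threshold,
    ``"ended_before_maturity"`` when weather ran out mid-season, and
    ``"ended_before_emergence"`` when the crop never emerged.
    """

    params: CropParameters
    days: list[DayRecord]
    status: str

    @property
    def final_state(self) -> CropState:
        return self.days[-1].state

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.days:
            s, f, d = rec.state, rec.flux, rec.derived
            rows.append({
                "date": rec.date.isoformat(), "day": rec.day_index,
                "eto": d.eto, "vpd": d.vpd, "gdd_inc": d.gdd_inc,
                "gdd_cum": s.gdd_cum, "stage": s.stage.value,
                "rain": f.rain, "irrigation": f.irrigation,
                "runoff": f.runoff, "drainage": f.drainage,
                "soil_evap": f.soil_evap, "transpiration": f.transpiration,
                "storage_start": f.storage_start, "storage_end": f.storage_end,
                "deficit_mm": rec.deficit_mm, "fi_rad": rec.fi_rad,
                "lai": s.lai, "ldm": s.ldm, "sdm": s.sdm, "hdm": s.hdm,
                "rdm": s.rdm, "agdm": s.agdm, "root_depth": s.root_depth,
                "si": s.si_today, "dm_inc": rec.dm_inc,
            })
        return pd.DataFrame(rows)


def simulate_season(params: CropParameters, weather: Sequence[WeatherDay],
                    soil: SoilProfile | None = None,
                    management: Management | None = None,
                    site: SiteInfo | None = None) -> SeasonResult:
    """Run the daily crop/soil simulation from sowing (first weather day).

    Per-day order of operations: derive weather (ETo, VPD, GDD); decide
    irrigation from the morning deficit; infiltrate rain + irrigation
    through the cascade; intercept radiation with the current canopy;
    partition ETo into soil evaporation (top layer) and transpiration
    (root zone, supply-limited); advance phenology; produce and partition
    dry matter; update leaf area and root depth. The simulation stops at
    maturity or when weather is exhausted; the daily water balance closes
    to 1e-9 mm throughout.
    """
    weather = list(weather)
    if not weather:
        raise InvalidInputError("empty weather series")
    soil = (soil or SoilProfile.default()).copy()
    management = management or Management()
    site = site or SiteInfo()
    deficit_depth = min(params.rd_max, soil.depth)

    state = CropState()
    records: list[DayRecord] = []
    status = "ended_before_emergence"

    for idx, day in enumerate(weather):
        eto = reference_eto(day, site)
        vpd = daily_vpd(day)
        gdd_inc = daily_gdd(day.t_max, day.t_min, params.t_base, params.t_cutoff)
        derived = DerivedWeather(eto=eto, vpd=vpd, gdd_inc=gdd_inc)

        irr = irrigation_decision(soil, management.mode, idx, deficit_depth,
                                  management.first_irrigation_day)
        storage_start = soil.storage_mm()
        drainage = infiltrate_cascade(soil, day.rain + irr)

        fi_rad = (fractional_interception(params.k_s, state.lai)
                  if state.lai > 0 else 0.0)
        e_pot, t_pot = partition_et(eto, fi_rad)
        e_act = extract_evaporation(soil, e_pot)
        t_act = extract_transpiration(soil, t_pot, state.root_depth,
                                      params.t_max_rate,
                                      params.stress_threshold)
        si = stress_index(t_act, min(t_pot, params.t_max_rate))
        state.si_today = si

        prev_emerged = state.gdd_cum >= params.gdd_emerge
        stage = advance_phenology(state, gdd_inc, si, params)
        if stage is Stage.EMERGED and not prev_emerged:
            # seed reserves appear as shoot mass, split leaf/stem at once
            cdm0 = params.dm_at_emergence
            state.ldm = cdm0 / (1.0 + params.p * cdm0)
            state.sdm = cdm0 - state.ldm
            state.lai = update_lai(state.ldm, params.sla)

        dm_inc = 0.0
        if stage.canopy_active:
            dm_inc = dm_increment(t_act, vpd, fi_rad, day.solar_rad, params)
            partition_dm(state, dm_inc, stage, params)
        state.root_depth = root_depth(state.gdd_cum, params)

        flux = WaterFluxDay(rain=day.rain, irrigation=irr, runoff=0.0,
                            drainage=drainage, soil_evap=e_act,
                            transpiration=t_act,
                            storage_start=storage_start,
                            storage_end=soil.storage_mm())
        records.append(DayRecord(date=day.date, day_index=idx, derived=derived,
                                 flux=flux, state=replace(state),
                                 fi_rad=fi_rad,
                                 deficit_mm=profile_deficit(soil, deficit_depth),
                                 dm_inc=dm_inc))
        if stage is Stage.MATURE:
            status = "mature"
            break
        if state.gdd_cum >= params.gdd_emerge:
            status = "ended_before_maturity"

    return SeasonResult(params=params, days=records, status=status)
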