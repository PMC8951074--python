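"""Layered cascading soil water store and the daily water-balance ledger.

The profile is an ordered stack of buckets. Infiltrating water fills each
layer to field capacity and spills downward; water leaving the bottom
layer is drainage (deep percolation). Evapotranspiration is partitioned by
canopy cover into soil evaporation (top layer only) and crop transpiration
(root zone, limited by plant-available water). The mass-balance ledger
mirrors the field water-balance bookkeeping::

    dS = Q_end - Q_start
    ET = P + I - R - D - dS

Runoff R is carried as an explicit always-zero column: the source trials
were on flat, bunded plots under drip irrigation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "WaterFluxDay",
    "et_from_balance",
    "infiltrate_cascade",
    "profile_deficit",
    "partition_et",
    "extract_transpiration",
    "extract_evaporation",
    "stress_index",
    "irrigation_decision",
    "IRRIGATION_INTERVALS",
]

MM_PER_M = 1000.0

#: Refill interval in days per management mode; ``rainfed`` never irrigates.
#: ``daily_refill`` is the idealised well-watered treatment used for
#: growth-analysis trials.
IRRIGATION_INTERVALS = {
    "daily_refill": 1,
    "weekly_refill": 7,
    "fortnightly_refill": 14,
}

IrrigationMode = Literal["daily_refill", "weekly_refill",
                         "fortnightly_refill", "rainfed"]


@dataclass
class SoilLayer:
    """One soil layer: geometry, water content and hydraulic limits.

    ``theta``, ``fc`` and ``pwp`` are volumetric water contents (m3 m-3);
    ``thickness`` in m; ``bulk_density`` in kg m-3. ``theta`` defaults to
    field capacity.
    """

    thickness: float
    fc: float
    pwp: float
    theta: float | None = None
    bulk_density: float = 1350.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidConfigError(f"layer thickness must be > 0: {self.thickness}")
        if not (0 < self.pwp < self.fc < 1):
            raise InvalidConfigError(
                f"require 0 < pwp < fc < 1, got pwp={self.pwp}, fc={self.fc}")
        if self.bulk_density <= 0:
            raise InvalidConfigError("bulk density must be positive")
        if self.theta is None:
            self.theta = self.fc
        if not (0 <= self.theta < 1):
            raise InvalidConfigError(f"theta out of [0, 1): {self.theta}")

    # -- water book-keeping helpers (all mm) --------------------------------
    @property
    def storage_mm(self) -> float:
        return self.theta * self.thickness * MM_PER_M

    @property
    def capacity_to_fc_mm(self) -> float:
        return max(0.0, (self.fc - self.theta) * self.thickness * MM_PER_M)

    @property
    def available_mm(self) -> float:
        """Plant-available water above permanent wilting point."""
        return max(0.0, (self.theta - self.pwp) * self.thickness * MM_PER_M)

    def add_mm(self, amount: float) -> None:
        self.theta += amount / (self.thickness * MM_PER_M)

    def remove_mm(self, amount: float) -> None:
        self.theta -= amount / (self.thickness * MM_PER_M)
        if self.theta < self.pwp - 1e-12:
            raise InvalidInputError("layer drawn below permanent wilting point")
        self.theta = max(self.theta, self.pwp)


@dataclass
class SoilProfile:
    """Ordered top-down stack of :class:`SoilLayer`.

    The default profile mirrors the measurement protocol of the source
    trials: five 0.20 m layers to 1.0 m, a sandy clay loam with
    fc = 0.27 and pwp = 0.13.
    """

    layers: list[SoilLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise InvalidConfigError("soil profile needs at least one layer")

    @classmethod
    def default(cls, n_layers: int = 5, thickness: float = 0.20,
                fc: float = 0.27, pwp: float = 0.13,
                theta: float | None = None,
                bulk_density: float = 1350.0) -> "SoilProfile":
        return cls([SoilLayer(thickness, fc, pwp, theta, bulk_density)
                    for _ in range(n_layers)])

    @property
    def depth(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    def storage_mm(self, depth: float | None = None) -> float:
        """Water stored (mm) over the top ``depth`` m (whole profile if None)."""
        if depth is None:
            return sum(layer.storage_mm for layer in self.layers)
        total, z = 0.0, 0.0
        for layer in self.layers:
            if z >= depth:
                break
            frac = min(layer.thickness, depth - z) / layer.thickness
            total += layer.storage_mm * frac
            z += layer.thickness
        return total

    def copy(self) -> "SoilProfile":
        return SoilProfile([replace(layer) for layer in self.layers])


@dataclass(frozen=True)
class WaterFluxDay:
    """One day's water-balance ledger row (all mm)."""

    rain: float
    irrigation: float
    runoff: float
    drainage: float
    soil_evap: float
    transpiration: float
    storage_start: float
    storage_end: float

    def __post_init__(self) -> None:
        for name in ("rain", "irrigation", "runoff", "drainage",
                     "soil_evap", "transpiration"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"negative water flux: {name}")
        if abs(self.closure_residual) > 1e-9:
            raise InvalidInputError(
                f"water balance does not close: residual "
                f"{self.closure_residual:.3e} mm")

    @property
    def closure_residual(self) -> float:
        inputs = self.rain + self.irrigation
        outputs = self.runoff + self.drainage + self.soil_evap + self.transpiration
        return inputs - outputs - (self.storage_end - self.storage_start)


def et_from_balance(p: float, i: float, r: float, d: float,
                    q_start: float, q_end: float) -> float:
    """Evapotranspiration as the residual of the root-zone water balance.

    ``ET = P + I - R - D - (Q_end - Q_start)``. A negative result signals a
    measurement inconsistency and is returned with a warning rather than
    raised, matching field practice where weekly storage readings carry
    instrument noise.
    """
    import math
    for name, v in (("p", p), ("i", i), ("r", r), ("d", d),
                    ("q_start", q_start), ("q_end", q_end)):
        if not math.isfinite(v):
            raise InvalidInputError(f"non-finite balance term: {name}")
    if min(p, i, r, d) < 0:
        raise InvalidInputError("P, I, R, D must all be >= 0")
    et = p + i - r - d - (q_end - q_start)
    if et < 0:
        warnings.warn(f"negative ET ({et:.1f} mm) from water balance; "
                      "inputs are likely inconsistent", stacklevel=2)
    return et


def infiltrate_cascade(profile: SoilProfile, water_in: float) -> float:
    """Infiltrate ``water_in`` mm from the top; return drainage (mm).

    Each layer absorbs up to its field-capacity deficit, the excess spills
    to the layer below; whatever passes the bottom layer drains. Water is
    conserved exactly: gains + drainage = water_in.
    """
    if water_in < 0:
        raise InvalidInputError(f"negative infiltration input: {water_in}")
    remaining = water_in
    for layer in profile.layers:
        if remaining <= 0:
            break
        absorbed = min(remaining, layer.capacity_to_fc_mm)
        if absorbed > 0:
            layer.add_mm(absorbed)
            remaining -= absorbed
    return remaining


def profile_deficit(profile: SoilProfile, depth: float | None = None) -> float:
    """Deficit to field capacity (mm) over the top ``depth`` m of profile.

    Layers partially inside ``depth`` contribute pro-rata; water above field
    capacity contributes zero (clamped), never a negative deficit.
    """
    if depth is None:
        depth = profile.depth
    if depth <= 0:
        raise InvalidInputError(f"depth must be positive: {depth}")
    if depth > profile.depth + 1e-9:
        raise InvalidInputError(
            f"depth {depth} m exceeds profile depth {profile.depth} m")
    total, z = 0.0, 0.0
    for layer in profile.layers:
        if z >= depth:
            break
        frac = min(layer.thickness, depth - z) / layer.thickness
        total += max(0.0, (layer.fc - layer.theta)) * layer.thickness * MM_PER_M * frac
        z += layer.thickness
    return total


def partition_et(eto: float, fi_rad: float) -> tuple[float, float]:
    """Split reference ET into potential soil evaporation and transpiration.

    The canopy claims its intercepted-radiation share: ``T_pot = FI * ETo``,
    ``E_pot = (1 - FI) * ETo``; the two always sum to ``ETo``.
    """
    if eto < 0:
        raise InvalidInputError(f"negative ETo: {eto}")
    if not (0 <= fi_rad < 1):
        raise InvalidInputError(f"fi_rad out of [0, 1): {fi_rad}")
    t_pot = fi_rad * eto
    return eto - t_pot, t_pot


def _root_zone_water(profile: SoilProfile, root_depth: float):
    """Per-layer (available, capacity) mm over the root zone, pro-rata."""
    rows, z = [], 0.0
    for layer in profile.layers:
        if z >= root_depth:
            break
        frac = min(layer.thickness, root_depth - z) / layer.thickness
        avail = layer.available_mm * frac
        cap = (layer.fc - layer.pwp) * layer.thickness * MM_PER_M * frac
        rows.append((layer, avail, cap))
        z += layer.thickness
    return rows


def extract_transpiration(profile: SoilProfile, t_pot: float,
                          root_depth: float, t_max_rate: float = 9.0,
                          stress_threshold: float = 0.30) -> float:
    """Remove actual transpiration from the root zone; return it (mm).

    Demand is potential transpiration capped at the crop's maximum daily
    rate. Supply scales with the root-zone plant-available water fraction
    ``f = (theta_bar - pwp) / (fc - pwp)``: unrestricted above the stress
    threshold, declining linearly to zero below it. Water is withdrawn from
    root-zone layers in proportion to each layer's available water, and no
    layer is drawn below wilting point.
    """
    if t_pot < 0:
        raise InvalidInputError(f"negative potential transpiration: {t_pot}")
    if root_depth <= 0:
        raise InvalidInputError(f"root depth must be positive: {root_depth}")
    if not (0 < stress_threshold < 1):
        raise InvalidInputError(
            f"stress threshold out of (0, 1): {stress_threshold}")
    rows = _root_zone_water(profile, root_depth)
    total_avail = sum(avail for _, avail, _ in rows)
    total_cap = sum(cap for _, _, cap in rows)
    if total_cap <= 0 or total_avail <= 0:
        return 0.0
    f = total_avail / total_cap
    demand = min(t_pot, t_max_rate)
    t_act = demand * min(1.0, f / stress_threshold)
    t_act = min(t_act, total_avail)
    if t_act <= 0:
        return 0.0
    for layer, avail, _ in rows:
        if avail > 0:
            layer.remove_mm(t_act * avail / total_avail)
    return t_act


def extract_evaporation(profile: SoilProfile, e_pot: float) -> float:
    """Remove soil evaporation from the top layer; return the actual amount.

    Supply-limited by the top layer's plant-available water; no staged
    surface-drying curve is applied.
    """
    if e_pot < 0:
        raise InvalidInputError(f"negative potential evaporation: {e_pot}")
    top = profile.layers[0]
    e_act = min(e_pot, top.available_mm)
    if e_act > 0:
        top.remove_mm(e_act)
    return e_act


def stress_index(t_act: float, t_pot: float) -> float:
    """Water stress index ``SI = 1 - T_act / T_pot`` in [0, 1].

    Zero when transpiration meets demand (ample water) and one when the
    crop cannot transpire at all. Zero demand means zero stress.
    """
    if t_pot < 0 or t_act < 0:
        raise InvalidInputError("transpiration terms must be >= 0")
    if t_act > t_pot + 1e-9:
        raise InvalidInputError(
            f"actual transpiration ({t_act}) exceeds potential ({t_pot})")
    if t_pot == 0:
        return 0.0
    return min(1.0, max(0.0, 1.0 - t_act / t_pot))


def irrigation_decision(profile: SoilProfile, mode: IrrigationMode,
                        day_index: int, root_depth: float,
                        first_irrigation_day: int | None = None) -> float:
    """Refill-to-field-capacity irrigation rule.

    On scheduled days the application equals the deficit to field capacity
    over ``root_depth``; otherwise zero. ``rainfed`` never irrigates.
    Scheduling starts at ``first_irrigation_day`` (default: one interval
    after sowing) and repeats every interval.
    """
    if mode == "rainfed":
        return 0.0
    if mode not in IRRIGATION_INTERVALS:
        raise InvalidInputError(f"unknown irrigation mode: {mode!r}")
    interval = IRRIGATION_INTERVALS[mode]
    first = interval if first_irrigation_day is None else first_irrigation_day
    if day_index < first or (day_index - first) % interval != 0:
        return 0.0
    return profile_deficit(profile, min(root_depth, profile.depth))
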