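"""Beer-Bouguer canopy light interception and extinction-coefficient algebra.

The canopy intercepts a fraction ``FI = 1 - exp(-K * LAI)`` of incoming
radiation. Ceptometer measurements give the PAR extinction coefficient
K_PAR; the model needs the coefficient for total solar radiation Ks, which
follows from K_PAR through the black-leaf diffuse coefficient and the
geometric mean of the leaf absorptances in the PAR and NIR bands
(Campbell & van Evert procedure)::

    K_bd = K_PAR / sqrt(a_p)
    a_s  = sqrt(a_p * a_n)
    Ks   = K_bd * sqrt(a_s)

With the standard absorptances a_p = 0.8 and a_n = 0.2 this collapses to
``Ks = K_PAR * sqrt(0.5)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidConfigError, InvalidInputError, MeasurementError

__all__ = [
    "CanopyOptics",
    "fractional_interception",
    "lai_from_interception",
    "fi_from_ceptometer",
    "kpar_to_ks",
]

#: Default leaf absorptance of photosynthetically active radiation.
DEFAULT_A_P = 0.8
#: Default leaf absorptance of near-infrared radiation.
DEFAULT_A_N = 0.2


def kpar_to_ks(k_par: float, a_p: float = DEFAULT_A_P,
               a_n: float = DEFAULT_A_N) -> float:
    """Convert a PAR extinction coefficient to the total-solar coefficient."""
    if k_par <= 0:
        raise InvalidConfigError(f"k_par must be positive, got {k_par}")
    if not (0 < a_p <= 1) or not (0 < a_n <= 1):
        raise InvalidConfigError(
            f"absorptances must be in (0, 1]: a_p={a_p}, a_n={a_n}")
    k_bd = k_par / math.sqrt(a_p)
    a_s = math.sqrt(a_p * a_n)
    return k_bd * math.sqrt(a_s)


@dataclass(frozen=True)
class CanopyOptics:
    """Radiation-extinction parameters of a crop canopy.

    ``k_s`` is always derived from ``k_par`` and the absorptances, never
    supplied directly.
    """

    k_par: float
    a_p: float = DEFAULT_A_P
    a_n: float = DEFAULT_A_N
    k_s: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.k_par <= 2):
            raise InvalidConfigError(f"k_par out of range (0, 2]: {self.k_par}")
        if not (0 < self.a_n <= self.a_p <= 1):
            raise InvalidConfigError(
                f"require 0 < a_n <= a_p <= 1, got a_p={self.a_p}, a_n={self.a_n}")
        object.__setattr__(self, "k_s", kpar_to_ks(self.k_par, self.a_p, self.a_n))


def fractional_interception(k: float, lai: float) -> float:
    """Fraction of incoming radiation intercepted by a canopy of given LAI.

    ``1 - exp(-k * lai)``; strictly increasing in both arguments, in [0, 1).
    For extreme ``k * lai`` the exponential underflows; the result is capped
    at the largest double below 1 to keep the half-open bound.
    """
    if k <= 0:
        raise InvalidInputError(f"extinction coefficient must be positive: {k}")
    if lai < 0:
        raise InvalidInputError(f"negative LAI: {lai}")
    return min(1.0 - math.exp(-k * lai), 1.0 - 2.0 ** -53)


def lai_from_interception(fi: float, k: float) -> float:
    """Invert the Beer-Bouguer law: LAI from fractional interception."""
    if k <= 0:
        raise InvalidInputError(f"extinction coefficient must be positive: {k}")
    if not (0 <= fi < 1):
        raise InvalidInputError(f"fractional interception out of [0, 1): {fi}")
    return -math.log(1.0 - fi) / k


def fi_from_ceptometer(par_above: float, par_below: float,
                       clamp: bool = False) -> float:
    """Fractional PAR interception from paired ceptometer readings.

    ``1 - below/above``. A below-canopy reading exceeding the above-canopy
    one is physically impossible; by default it raises
    :class:`MeasurementError`, with ``clamp=True`` it is truncated to full
    transmission (FI = 0).
    """
    if par_above <= 0:
        raise InvalidInputError(f"above-canopy PAR must be positive: {par_above}")
    if par_below < 0:
        raise InvalidInputError(f"negative below-canopy PAR: {par_below}")
    if par_below > par_above:
        if not clamp:
            raise MeasurementError(
                f"below-canopy PAR ({par_below}) exceeds above-canopy "
                f"({par_above})")
        par_below = par_above
    return 1.0 - par_below / par_above
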