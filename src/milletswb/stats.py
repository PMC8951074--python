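"""Goodness-of-fit statistics for model evaluation.

Three statistics conventionally reported for soil-water and crop-growth
simulations: the ordinary coefficient of determination (squared Pearson
correlation), the Willmott index of agreement D in [0, 1], and the mean
absolute error expressed as a percentage of the observed mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, UndefinedStatisticError

__all__ = ["FitStatistics", "r_squared", "willmott_d", "mae_percent",
           "evaluate"]

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitStatistics:
    r_squared: float
    willmott_d: float
    mae_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.willmott_d <= 1.0):
            raise InvalidInputError(f"D out of [0, 1]: {self.willmott_d}")
        if self.mae_percent < 0:
            raise InvalidInputError("MAE% must be >= 0")


def _paired(observed: Sequence[float], simulated: Sequence[float]):
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise InvalidInputError("observed and simulated differ in length")
    if obs.size < 2:
        raise InvalidInputError("need at least 2 paired values")
    return obs, sim


def r_squared(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and simulated series."""
    obs, sim = _paired(observed, simulated)
    if np.all(obs == obs[0]):
        raise UndefinedStatisticError("observed series is constant")
    if np.all(sim == sim[0]):
        raise UndefinedStatisticError("simulated series is constant")
    r = float(np.corrcoef(obs, sim)[0, 1])
    return r * r


def willmott_d(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Willmott index of agreement, bounded [0, 1], 1 = perfect.

    ``d = 1 - sum((sim-obs)^2) / sum((|sim-obar| + |obs-obar|)^2)`` with
    ``obar`` the observed mean. When every value in both series is
    identical the denominator vanishes and d = 1 by convention.
    """
    obs, sim = _paired(observed, simulated)
    obar = float(np.mean(obs))
    denom = float(np.sum((np.abs(sim - obar) + np.abs(obs - obar)) ** 2))
    if denom == 0.0:
        _log.info("willmott_d: zero denominator (identical constant series); "
                  "returning 1 by convention")
        return 1.0
    d = 1.0 - float(np.sum((sim - obs) ** 2)) / denom
    return min(1.0, max(0.0, d))  # guard float dust at the [0, 1] edges


def mae_percent(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Mean absolute error as a percentage of the observed mean."""
    obs, sim = _paired(observed, simulated)
    obar = float(np.mean(obs))
    if obar == 0.0:
        raise UndefinedStatisticError("observed mean is zero; MAE% undefined")
    return 100.0 * float(np.mean(np.abs(sim - obs))) / abs(obar)


def evaluate(observed: Sequence[float],
             simulated: Sequence[float]) -> FitStatistics:
    """All three statistics at once."""
    return FitStatistics(r_squared=r_squared(observed, simulated),
                         willmott_d=willmott_d(observed, simulated),
                         mae_percent=mae_percent(observed, simulated))
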