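"""Thermal-time flowering model for the primary strawberry inflorescence.

An inflorescence carries up to ``flw_limit`` (default 7) flowers that open
sequentially.  Development from the 1st to the last flower is driven by
accumulated daily mean temperature: each day contributes

    d_b(t) = T(t) / ct_ff * (flw_limit - 1)

development units, where ``ct_ff`` (252.1 degC*day) is the cumulative
temperature needed to progress from the 1st to the 7th flower.  The j-th
flower opens on the first day the running sum B(t), accumulated from the
observed first-flowering date (inclusive), reaches j - 1.  Observed flowering
dates always override model predictions.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np

from .temperature import TemperatureSeries

__all__ = [
    "PhenologyParams",
    "FruitRecord",
    "FloweringForecast",
    "bunch_development_increment",
    "daily_increments",
    "cumulative_development",
    "predict_flowering_dates",
    "merge_observed_flowering",
]


@dataclass(frozen=True)
class PhenologyParams:
    """Parameters of the inflorescence development clock.

    ct_ff
        Cumulative temperature for 1st -> 7th flower development, degC*day.
    flw_limit
        Maximum number of flowers retained per inflorescence; later flowers
        are removed and never simulated.
    """

    ct_ff: float = 252.1
    flw_limit: int = 7

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_ff) and self.ct_ff > 0):
            raise ValueError(f"ct_ff must be positive and finite, got {self.ct_ff}")
        if not isinstance(self.flw_limit, (int, np.integer)) or self.flw_limit < 2:
            raise ValueError(f"flw_limit must be an integer >= 2, got {self.flw_limit}")


@dataclass(frozen=True)
class FruitRecord:
    """One tagged fruit: flower order on its inflorescence plus the observed
    and/or predicted flowering and harvest dates.

    Downstream code always uses the observed date when present and falls back
    to the prediction (``effective_*`` properties).
    """

    plant_id: str
    flower_order: int
    flowering_observed: Optional[dt.date] = None
    flowering_predicted: Optional[dt.date] = None
    harvest_observed: Optional[dt.date] = None
    harvest_predicted: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.flower_order < 1:
            raise ValueError(f"flower_order must be >= 1, got {self.flower_order}")
        if self.harvest_observed is not None:
            flw = self.effective_flowering
            if flw is None:
                raise ValueError(
                    f"fruit {self.plant_id}/{self.flower_order}: observed harvest "
                    "without any flowering date"
                )
            if self.harvest_observed < flw:
                raise ValueError(
                    f"fruit {self.plant_id}/{self.flower_order}: harvest "
                    f"{self.harvest_observed} precedes flowering {flw}"
                )

    @property
    def effective_flowering(self) -> Optional[dt.date]:
        return self.flowering_observed or self.flowering_predicted

    @property
    def effective_harvest(self) -> Optional[dt.date]:
        return self.harvest_observed or self.harvest_predicted


@dataclass(frozen=True)
class FloweringForecast:
    """Predicted flowering dates for flowers 2..flw_limit of one inflorescence.

    ``dates`` maps flower order j to the predicted date; ``unresolved`` lists
    orders whose development threshold was not reached within the temperature
    horizon (reported, never silently dropped).
    """

    first_flowering: dt.date
    dates: Mapping[int, dt.date]
    unresolved: frozenset[int]


def bunch_development_increment(temp_c: float, params: PhenologyParams = PhenologyParams()) -> float:
    """Daily increment in bunch development at mean temperature ``temp_c``.

    Negative daily means contribute zero development (biological floor).
    """
    if not np.isfinite(temp_c):
        raise ValueError(f"non-finite temperature: {temp_c}")
    return max(float(temp_c), 0.0) / params.ct_ff * (params.flw_limit - 1)


def daily_increments(
    temps: TemperatureSeries,
    t0: dt.date,
    t_end: dt.date,
    params: PhenologyParams = PhenologyParams(),
) -> np.ndarray:
    """Vector of d_b over the inclusive window [t0, t_end]."""
    window = temps.window(t0, t_end)
    return np.maximum(window, 0.0) / params.ct_ff * (params.flw_limit - 1)


def cumulative_development(
    temps: TemperatureSeries,
    t0: dt.date,
    t: dt.date,
    params: PhenologyParams = PhenologyParams(),
) -> float:
    """Cumulative development index B(t), summed over [t0, t] inclusive.

    The first-flowering day itself contributes; B is nondecreasing in ``t``
    for nonnegative temperatures.
    """
    if t < t0:
        raise ValueError(f"t ({t}) precedes t0 ({t0})")
    return float(daily_increments(temps, t0, t, params).sum())


def predict_flowering_dates(
    first_flowering: dt.date,
    temps: TemperatureSeries,
    params: PhenologyParams = PhenologyParams(),
) -> FloweringForecast:
    """Predict flowering dates of flowers j = 2..flw_limit.

    Flower j opens on the earliest day t with B(t) >= j - 1, where B
    accumulates from ``first_flowering``.  The horizon is the end of the
    temperature series; thresholds not reached by then are reported in
    ``unresolved``.
    """
    incs = daily_increments(temps, first_flowering, temps.end, params)
    b = np.cumsum(incs)
    orders = np.arange(2, params.flw_limit + 1)
    # b is nondecreasing (increments >= 0), so searchsorted finds the first
    # crossing; side="left" gives the earliest index with b >= threshold.
    idx = np.searchsorted(b, orders - 1, side="left")
    dates: dict[int, dt.date] = {}
    unresolved: set[int] = set()
    for j, i in zip(orders, idx):
        if i < b.size:
            dates[int(j)] = first_flowering + dt.timedelta(days=int(i))
        else:
            unresolved.add(int(j))
    return FloweringForecast(first_flowering, dates, frozenset(unresolved))


def merge_observed_flowering(
    records: Iterable[FruitRecord],
    forecasts: Mapping[str, FloweringForecast],
) -> list[FruitRecord]:
    """Fill each record's predicted flowering from its plant's forecast.

    The observed date, when present, always wins downstream; predictions only
    back-fill missing observations.  Records whose plant has no forecast and
    no observation stay unresolved (both fields None).
    """
    merged: list[FruitRecord] = []
    for rec in records:
        forecast = forecasts.get(rec.plant_id)
        predicted = rec.flowering_predicted
        if forecast is not None:
            if rec.flower_order == 1:
                predicted = forecast.first_flowering
            else:
                predicted = forecast.dates.get(rec.flower_order, predicted)
            if (
                rec.flowering_observed is not None
                and rec.flowering_observed < forecast.first_flowering
            ):
                warnings.warn(
                    f"fruit {rec.plant_id}/{rec.flower_order}: observed flowering "
                    f"{rec.flowering_observed} precedes the inflorescence's first "
                    f"flowering {forecast.first_flowering}",
                    stacklevel=2,
                )
        merged.append(replace(rec, flowering_predicted=predicted))
    return merged
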