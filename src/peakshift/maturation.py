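"""Fruit maturation: from flowering date to harvest date.

Two model families are supported:

* ``thermal_threshold`` (default): the fruit is harvest-ripe on the first day
  the cumulative daily mean temperature, accumulated from the day *after*
  flowering, reaches a heat threshold (default 600 degC*day).  This is the
  classical accumulated-temperature rule for strawberry and keeps, e.g.,
  600 / 15 degC = exactly 40 days.

* ``stage_regression``: the flowering-to-harvest period is split into four
  developmental stages (flowering, green, white, turning); each stage's
  duration is a user-supplied function of the mean air temperature over that
  stage.  Because the stage mean depends on the stage's own (unknown)
  duration, each stage is solved by fixed-point iteration.  The published
  stage coefficients live in earlier strawberry ripening literature and are
  not bundled here; the shipped example coefficients are illustrative only.

Observed harvest dates always override predictions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional

import numpy as np

from .phenology import FruitRecord
from .temperature import TemperatureSeries

__all__ = [
    "STAGES",
    "StageDuration",
    "MaturationModel",
    "StageInterval",
    "StageTrace",
    "HarvestPrediction",
    "ConvergenceError",
    "predict_harvest_date",
    "predict_harvest_indices",
    "merge_observed_harvest",
]

STAGES = ("flowering", "green", "white", "turning")

_FAMILIES: dict[str, Callable[..., float]] = {
    "constant": lambda at, c: c,
    "linear": lambda at, a, b: a + b * at,
    # a / (at - b): duration shrinks hyperbolically as temperature rises
    "reciprocal_linear": lambda at, a, b: a / (at - b),
}


@dataclass(frozen=True)
class StageDuration:
    """Duration model for one developmental stage: days as a function of the
    stage-mean air temperature (degC)."""

    family: str
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown duration family {self.family!r}; choose from {sorted(_FAMILIES)}"
            )
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    def __call__(self, at_c: float) -> float:
        days = float(_FAMILIES[self.family](at_c, *self.coefficients))
        if not np.isfinite(days):
            raise ValueError(f"stage duration not finite at {at_c} degC")
        return days


@dataclass(frozen=True)
class MaturationModel:
    """Pluggable harvest-duration model (see module docstring)."""

    kind: str = "thermal_threshold"
    threshold: float = 600.0
    stage_params: Optional[Mapping[str, StageDuration]] = None

    def __post_init__(self) -> None:
        if self.kind == "thermal_threshold":
            if not (np.isfinite(self.threshold) and self.threshold > 0):
                raise ValueError(f"threshold must be positive, got {self.threshold}")
        elif self.kind == "stage_regression":
            if self.stage_params is None or set(self.stage_params) != set(STAGES):
                raise ValueError(f"stage_regression requires all four stages {STAGES}")
            for stage, fn in self.stage_params.items():
                for at in np.linspace(5.0, 30.0, 26):
                    if fn(float(at)) < 1.0:
                        raise ValueError(
                            f"stage {stage!r} duration < 1 day at {at:.1f} degC "
                            "(operating range 5-30 degC)"
                        )
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @classmethod
    def thermal_threshold(cls, threshold: float = 600.0) -> "MaturationModel":
        return cls(kind="thermal_threshold", threshold=threshold)

    @classmethod
    def stage_regression(cls, stage_params: Mapping[str, StageDuration]) -> "MaturationModel":
        return cls(kind="stage_regression", stage_params=dict(stage_params))


@dataclass(frozen=True)
class StageInterval:
    stage: str
    entry: dt.date
    exit: dt.date
    mean_temp: float


@dataclass(frozen=True)
class StageTrace:
    """Audit trail of the stage decomposition behind one harvest prediction.

    The thermal-threshold model emits a single pseudo-stage spanning the whole
    flowering-to-harvest window.
    """

    intervals: tuple[StageInterval, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.entry != a.exit:
                raise ValueError("stages must be contiguous")


@dataclass(frozen=True)
class HarvestPrediction:
    """Predicted harvest date, or an unresolved marker when the temperature
    horizon ran out first (``date`` None, ``accumulated_fraction`` < 1)."""

    date: Optional[dt.date]
    trace: Optional[StageTrace] = None
    accumulated_fraction: float = 1.0


class ConvergenceError(RuntimeError):
    """Stage-duration fixed point failed to converge."""


def predict_harvest_indices(
    temps: np.ndarray, flowering_idx: np.ndarray, threshold: float
) -> np.ndarray:
    """Vectorized thermal-threshold harvest solver on a raw temperature array.

    For each flowering index i, returns the smallest index h with
    sum(temps[i+1 .. h]) >= threshold, or -1 if the array ends first.
    Requires strictly positive temperatures (the operating regime of a heated
    chamber); falls back to a day loop otherwise.
    """
    temps = np.asarray(temps, dtype=float)
    flowering_idx = np.asarray(flowering_idx, dtype=int)
    c = np.concatenate(([0.0], np.cumsum(temps)))  # c[k] = sum temps[0..k-1]
    if np.all(temps > 0):
        # c strictly increasing -> searchsorted finds the first crossing
        targets = c[flowering_idx + 1] + threshold
        h = np.searchsorted(c, targets, side="left") - 1
        h[h >= temps.size] = -1
        return h
    out = np.full(flowering_idx.shape, -1, dtype=int)
    for k, i in enumerate(flowering_idx):
        acc = 0.0
        for h in range(i + 1, temps.size):
            acc += temps[h]
            if acc >= threshold:
                out[k] = h
                break
    return out


def _predict_thermal(
    flowering: dt.date, temps: TemperatureSeries, model: MaturationModel
) -> HarvestPrediction:
    i = temps.index_of(flowering)
    h = int(predict_harvest_indices(temps.values, np.array([i]), model.threshold)[0])
    if h < 0:
        acc = float(temps.values[i + 1 :].sum())
        return HarvestPrediction(None, None, min(acc / model.threshold, 1.0))
    harvest = temps.date_at(h)
    mean_t = float(np.mean(temps.values[i + 1 : h + 1]))
    trace = StageTrace((StageInterval("thermal", flowering, harvest, mean_t),))
    return HarvestPrediction(harvest, trace)


def _predict_stages(
    flowering: dt.date,
    temps: TemperatureSeries,
    model: MaturationModel,
    tol_days: float = 0.5,
    max_iter: int = 20,
) -> HarvestPrediction:
    assert model.stage_params is not None
    intervals: list[StageInterval] = []
    entry = flowering
    for k, stage in enumerate(STAGES):
        fn = model.stage_params[stage]
        if not temps.covers(entry):
            return HarvestPrediction(None, None, k / len(STAGES))
        # Fixed point: duration n depends on the mean temperature over the
        # window of length n it itself defines.
        n = fn(temps.value_on(entry))
        mean_t = temps.value_on(entry)
        for _ in range(max_iter):
            days = max(1, int(round(n)))
            last = entry + dt.timedelta(days=days - 1)
            if not temps.covers(last):
                return HarvestPrediction(None, None, k / len(STAGES))
            mean_t = float(np.mean(temps.window(entry, last)))
            n_new = fn(mean_t)
            if abs(n_new - n) <= tol_days:
                n = n_new
                break
            n = n_new
        else:
            raise ConvergenceError(
                f"stage {stage!r} duration did not converge at entry {entry}"
            )
        days = max(1, int(round(n)))
        exit_ = entry + dt.timedelta(days=days)
        intervals.append(StageInterval(stage, entry, exit_, mean_t))
        entry = exit_
    return HarvestPrediction(entry, StageTrace(tuple(intervals)))


def predict_harvest_date(
    flowering: dt.date,
    temps: TemperatureSeries,
    model: MaturationModel = MaturationModel(),
) -> HarvestPrediction:
    """Predict the harvest date of a fruit that flowered on ``flowering``.

    Thermal accumulation starts the day after flowering; harvest is the first
    day the running sum reaches the threshold.  Raising every future daily
    temperature never delays the predicted date (the monotonicity the
    temperature-offset controller relies on).
    """
    if model.kind == "thermal_threshold":
        return _predict_thermal(flowering, temps, model)
    return _predict_stages(flowering, temps, model)


def merge_observed_harvest(
    records: Iterable[FruitRecord],
    predictions: Mapping[tuple[str, int], HarvestPrediction],
) -> tuple[list[FruitRecord], float]:
    """Back-fill predicted harvests; observations win downstream.

    Returns the updated records and the share of fruits whose harvest is
    observed — the quantity that makes the closed loop converge onto the
    realized distribution late in the season.
    """
    merged: list[FruitRecord] = []
    n_obs = 0
    n_dated = 0
    for rec in records:
        pred = predictions.get((rec.plant_id, rec.flower_order))
        predicted = rec.harvest_predicted
        if pred is not None and pred.date is not None:
            predicted = pred.date
        if rec.harvest_observed is not None:
            n_obs += 1
        if rec.harvest_observed is not None or predicted is not None:
            n_dated += 1
        merged.append(replace(rec, harvest_predicted=predicted))
    share = n_obs / n_dated if n_dated else 0.0
    return merged, share
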