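"""Feedback harvest-peak controller.

At each scheduled update the controller (i) re-predicts the population
harvest peak from everything known so far — observed flowering/harvest dates
plus thermal-time predictions for the rest — under the temperatures realized
to date, (ii) computes the residual dd = predicted peak - target date, and
(iii) exhaustively searches a temperature offset dT in [-5, +5] degC on a
0.1 degC grid, assuming the candidate offset is applied uniformly from the
current date to the horizon.  Among candidates minimizing |dd| it picks the
smallest |dT| (remaining tie: the cooling side), writes the offset into the
piecewise-constant actuation schedule, and lets the chamber run until the
next update.

Positive residuals (late peak) call for heating (dT > 0); negative for
cooling — the sign logic follows from maturation monotonicity, not from any
hard-coded rule.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distribution import (
    DEFAULT_KERNEL_SD,
    HarvestDistribution,
    estimate_distribution,
    find_peak,
)
from .maturation import MaturationModel, predict_harvest_date, predict_harvest_indices
from .phenology import FruitRecord, PhenologyParams, predict_flowering_dates
from .temperature import TemperatureSeries

__all__ = [
    "ControlConfig",
    "OffsetSchedule",
    "ControlState",
    "UpdateLog",
    "ControlResult",
    "compute_residual",
    "effective_temperatures",
    "predict_peak_under_offset",
    "search_offset",
    "run_control_loop",
]

ONE_DAY = dt.timedelta(days=1)


@dataclass(frozen=True)
class ControlConfig:
    """Target, search grid, and update calendar of the peak-shift loop.

    Defaults mirror the proof-of-concept chamber campaign: target virtual
    Dec 21, intervention from Nov 30, updates 2-3 times per week through
    Dec 28, offsets searched over [-5, +5] degC in 0.1 degC steps.
    """

    target_date: dt.date = dt.date(2019, 12, 21)
    search_min: float = -5.0
    search_max: float = 5.0
    search_step: float = 0.1
    intervention_start: dt.date = dt.date(2019, 11, 30)
    update_dates: tuple[dt.date, ...] = (
        dt.date(2019, 12, 4),
        dt.date(2019, 12, 7),
        dt.date(2019, 12, 11),
        dt.date(2019, 12, 14),
        dt.date(2019, 12, 18),
        dt.date(2019, 12, 21),
        dt.date(2019, 12, 25),
        dt.date(2019, 12, 28),
    )
    horizon_end: dt.date = dt.date(2020, 1, 31)
    stop_after_target: bool = False

    def __post_init__(self) -> None:
        if not self.search_min < 0 < self.search_max:
            raise ValueError("search bounds must straddle zero")
        if self.search_step <= 0:
            raise ValueError("search_step must be positive")
        dates = list(self.update_dates)
        if dates != sorted(set(dates)):
            raise ValueError("update_dates must be strictly increasing")
        if dates and dates[0] < self.intervention_start:
            raise ValueError("update_dates must not precede intervention_start")

    @property
    def candidates(self) -> np.ndarray:
        """Offset grid, inclusive of both endpoints (101 points by default)."""
        n = int(round((self.search_max - self.search_min) / self.search_step))
        grid = self.search_min + self.search_step * np.arange(n + 1)
        return np.round(grid, 6)

    def schedule_dates(self) -> list[dt.date]:
        dates = [self.intervention_start, *self.update_dates]
        if self.stop_after_target:
            dates = [d for d in dates if d <= self.target_date]
        return sorted(set(dates))


@dataclass
class OffsetSchedule:
    """Piecewise-constant date -> dT map; zero before the first breakpoint."""

    breakpoints: list[tuple[dt.date, float]] = field(default_factory=list)

    def offset_on(self, day: dt.date) -> float:
        value = 0.0
        for start, dT in self.breakpoints:
            if day >= start:
                value = dT
            else:
                break
        return value

    def set_from(self, day: dt.date, dT: float) -> None:
        """Apply ``dT`` from ``day`` onward (overwrites later breakpoints)."""
        self.breakpoints = [bp for bp in self.breakpoints if bp[0] < day]
        self.breakpoints.append((day, float(dT)))

    def daily_offsets(self, start: dt.date, n_days: int) -> np.ndarray:
        out = np.zeros(n_days)
        for bp_start, dT in self.breakpoints:
            i = max((bp_start - start).days, 0)
            if i < n_days:
                out[i:] = dT
        return out

    def apply_to(self, series: TemperatureSeries) -> TemperatureSeries:
        return series.plus(self.daily_offsets(series.start, len(series)))

    def max_abs(self) -> float:
        return max((abs(dT) for _, dT in self.breakpoints), default=0.0)


@dataclass
class ControlState:
    """Everything the controller knows at one update instant."""

    current_date: dt.date
    records: list[FruitRecord]
    baseline: TemperatureSeries
    applied: OffsetSchedule
    residual_history: list[tuple[dt.date, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            for obs in (rec.flowering_observed, rec.harvest_observed):
                if obs is not None and obs > self.current_date:
                    raise ValueError(
                        f"observation dated {obs} lies after current date "
                        f"{self.current_date}"
                    )


def compute_residual(predicted_peak: dt.date, target: dt.date) -> int:
    """Residual dd in days; positive means the peak is late."""
    return (predicted_peak - target).days


def effective_temperatures(
    state: ControlState, candidate_dT: float, horizon_end: dt.date
) -> TemperatureSeries:
    """Realized past (baseline + applied offsets) up to the current date,
    baseline + candidate offset from the current date to the horizon."""
    base = state.baseline
    n = base.index_of(horizon_end) + 1
    values = base.values[:n] + state.applied.daily_offsets(base.start, n)
    i_now = base.index_of(state.current_date)
    values[i_now:] = base.values[i_now:n] + candidate_dT
    return TemperatureSeries(base.start, values)


def _effective_harvest_dates(
    records: Sequence[FruitRecord],
    temps: TemperatureSeries,
    model: MaturationModel,
    params: PhenologyParams,
) -> list[dt.date]:
    """Observed-else-predicted harvest date per fruit (unresolved excluded).

    Flowering for flowers without an observation is predicted from the
    plant's first flowering via the thermal ladder under ``temps``.
    """
    first_flowering: dict[str, dt.date] = {}
    for rec in records:
        if rec.flower_order == 1 and rec.effective_flowering is not None:
            first_flowering[rec.plant_id] = rec.effective_flowering

    forecasts = {
        pid: predict_flowering_dates(f0, temps, params)
        for pid, f0 in first_flowering.items()
    }

    harvest_dates: list[dt.date] = []
    pending: list[dt.date] = []  # flowering dates still needing a harvest prediction
    for rec in records:
        if rec.flower_order > params.flw_limit:
            continue
        if rec.harvest_observed is not None:
            harvest_dates.append(rec.harvest_observed)
            continue
        flw = rec.flowering_observed
        if flw is None:
            forecast = forecasts.get(rec.plant_id)
            if forecast is None:
                continue
            if rec.flower_order == 1:
                flw = forecast.first_flowering
            else:
                flw = forecast.dates.get(rec.flower_order)
        if flw is None or not temps.covers(flw):
            continue
        pending.append(flw)

    if pending:
        if model.kind == "thermal_threshold":
            idx = np.array([temps.index_of(f) for f in pending])
            h = predict_harvest_indices(temps.values, idx, model.threshold)
            harvest_dates.extend(temps.date_at(int(k)) for k in h if k >= 0)
        else:
            for f in pending:
                pred = predict_harvest_date(f, temps, model)
                if pred.date is not None:
                    harvest_dates.append(pred.date)
    return harvest_dates


def predict_peak_under_offset(
    state: ControlState,
    candidate_dT: float,
    model: MaturationModel = MaturationModel(),
    params: PhenologyParams = PhenologyParams(),
    kernel_sd: float = DEFAULT_KERNEL_SD,
    horizon_end: Optional[dt.date] = None,
) -> dt.date:
    """Predicted population harvest-peak date with ``candidate_dT`` applied
    uniformly from the current date onward."""
    horizon = horizon_end or state.baseline.end
    temps = effective_temperatures(state, candidate_dT, horizon)
    dates = _effective_harvest_dates(state.records, temps, model, params)
    if not dates:
        raise ValueError("no resolvable fruit: cannot predict a harvest peak")
    return find_peak(estimate_distribution(dates, kernel_sd)).peak_date


def search_offset(
    state: ControlState,
    config: ControlConfig,
    model: MaturationModel = MaturationModel(),
    params: PhenologyParams = PhenologyParams(),
    kernel_sd: float = DEFAULT_KERNEL_SD,
) -> tuple[float, int]:
    """Exhaustive grid search for the offset driving the residual to zero.

    Every candidate is evaluated; ties on |dd| break to the smallest |dT|,
    then to the more negative (cooling) side.  Returns the chosen offset and
    its predicted residual.
    """
    candidates = config.candidates
    if candidates.size == 0:
        raise ValueError("empty candidate grid")
    best: Optional[tuple[float, float, float]] = None
    best_pair: tuple[float, int] = (0.0, 0)
    for dT in candidates:
        peak = predict_peak_under_offset(
            state, float(dT), model, params, kernel_sd, config.horizon_end
        )
        dd = compute_residual(peak, config.target_date)
        key = (abs(dd), abs(dT), float(dT))
        if best is None or key < best:
            best = key
            best_pair = (float(dT), dd)
    return best_pair


@dataclass(frozen=True)
class UpdateLog:
    date: dt.date
    residual_days: int
    chosen_offset: float


@dataclass(frozen=True)
class ControlResult:
    """Outcome of one closed-loop season."""

    schedule: OffsetSchedule
    history: tuple[UpdateLog, ...]
    final_distribution: HarvestDistribution
    realized_peak: dt.date
    terminal_residual_days: int


def run_control_loop(
    emulator,
    config: ControlConfig = ControlConfig(),
    model: MaturationModel = MaturationModel(),
    params: PhenologyParams = PhenologyParams(),
    kernel_sd: float = DEFAULT_KERNEL_SD,
    control_enabled: bool = True,
) -> ControlResult:
    """Run the full simulation-in-the-loop season against an emulator.

    With ``control_enabled`` False the loop degenerates to the uncorrected
    control treatment: the schedule stays identically zero and the residual
    is merely logged at each update.
    """
    schedule = OffsetSchedule()
    history: list[UpdateLog] = []
    for day in config.schedule_dates():
        # Advance only through yesterday: the offset chosen at this update
        # takes effect on the update day itself, exactly as the search assumes.
        records = emulator.advance_to(day - ONE_DAY, schedule)
        state = ControlState(day, records, emulator.baseline, schedule)
        if control_enabled:
            dT, dd = search_offset(state, config, model, params, kernel_sd)
            schedule.set_from(day, dT)
        else:
            dT = 0.0
            peak = predict_peak_under_offset(
                state, 0.0, model, params, kernel_sd, config.horizon_end
            )
            dd = compute_residual(peak, config.target_date)
        history.append(UpdateLog(day, dd, dT))

    records = emulator.advance_to(config.horizon_end, schedule)
    realized = [r.harvest_observed for r in records if r.harvest_observed is not None]
    if not realized:
        raise RuntimeError("emulator revealed no harvests before the horizon")
    dist = estimate_distribution(realized, kernel_sd)
    peak = find_peak(dist).peak_date
    return ControlResult(
        schedule=schedule,
        history=tuple(history),
        final_distribution=dist,
        realized_peak=peak,
        terminal_residual_days=compute_residual(peak, config.target_date),
    )
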