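"""Virtual climate chamber and plant population.

Synthetic stand-in for the chamber experiments: it (i) generates a baseline
daily-temperature profile matching the published summary statistics of the
reproduced greenhouse season (pre-period fixed at 19 degC to promote first
bloom; regulation period mean 13.62 degC, SD 1.99 degC, clamped to the
observed 8.65-18.19 degC range), (ii) instantiates cooling (CL, flowering a
week early), heating (HT, a week late) or control (CT) scenarios, and (iii)
advances a population of virtual plants day by day under the applied
temperature schedule, revealing flowering and harvest events as daily
observations.

Plant ground truth follows the same thermal-time models as the predictor
(with optional per-fruit day jitter), so a zero-noise run is a perfect-model
closed loop that isolates controller behaviour from model error.  Scenario
first-flowering dates are back-calculated so that the uncorrected population
peak lands on the reference date; the flowering shift then moves it by the
scenario's +/- 7 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .controller import OffsetSchedule
from .distribution import DEFAULT_KERNEL_SD, estimate_distribution, find_peak
from .maturation import MaturationModel, predict_harvest_indices
from .phenology import FruitRecord, PhenologyParams, bunch_development_increment
from .temperature import TemperatureSeries

__all__ = [
    "VIRTUAL_SEASON_START",
    "REGULATION_START",
    "VIRTUAL_SEASON_END",
    "DEFAULT_ANCHOR",
    "ScenarioConfig",
    "ChamberEmulator",
    "generate_baseline_temperature",
    "back_calculate_first_flowering",
    "map_virtual_date",
    "map_real_date",
]

ONE_DAY = dt.timedelta(days=1)

# Virtual 2019 reference season shared by all scenarios.
VIRTUAL_SEASON_START = dt.date(2019, 10, 1)
REGULATION_START = dt.date(2019, 11, 14)
VIRTUAL_SEASON_END = dt.date(2020, 1, 31)

# Real chamber start of the first campaign mapped onto the virtual calendar.
DEFAULT_ANCHOR = (dt.date(2022, 4, 28), dt.date(2019, 11, 14))

_SHIFT_BY_KIND = {"CL": -7, "HT": 7, "CT": 0}


def map_virtual_date(real: dt.date, anchor: tuple[dt.date, dt.date] = DEFAULT_ANCHOR) -> dt.date:
    """Affine real -> virtual calendar mapping (day offsets preserved)."""
    real_ref, virtual_ref = anchor
    return virtual_ref + (real - real_ref)


def map_real_date(virtual: dt.date, anchor: tuple[dt.date, dt.date] = DEFAULT_ANCHOR) -> dt.date:
    """Inverse of :func:`map_virtual_date`; round-trips exactly."""
    real_ref, virtual_ref = anchor
    return real_ref + (virtual - virtual_ref)


def generate_baseline_temperature(
    seed: int,
    pre_period_temp: float = 19.0,
    reg_mean: float = 13.62,
    reg_sd: float = 1.99,
    clamp: tuple[float, float] = (8.65, 18.19),
    start: dt.date = VIRTUAL_SEASON_START,
    reg_start: dt.date = REGULATION_START,
    end: dt.date = VIRTUAL_SEASON_END,
    ar_phi: float = 0.7,
    trend_span_c: float = 3.0,
) -> TemperatureSeries:
    """Synthesize the season's baseline daily-mean temperature profile.

    Pre-period (flower-promotion) days are fixed at ``pre_period_temp``.  The
    regulation segment is a declining linear autumn->winter trend plus AR(1)
    day-to-day noise, affinely rescaled to the target mean/SD and clamped to
    the stated range.  Deterministic per seed.
    """
    lo, hi = clamp
    if lo >= hi:
        raise ValueError(f"clamp bounds inverted: {clamp}")
    if not start <= reg_start <= end:
        raise ValueError("require start <= reg_start <= end")
    rng = np.random.default_rng(seed)
    n_pre = (reg_start - start).days
    n_reg = (end - reg_start).days + 1
    trend = np.linspace(trend_span_c / 2, -trend_span_c / 2, n_reg)
    noise = np.empty(n_reg)
    e = rng.standard_normal(n_reg)
    noise[0] = e[0]
    for i in range(1, n_reg):
        noise[i] = ar_phi * noise[i - 1] + e[i]
    raw = trend + noise
    z = (raw - raw.mean()) / raw.std()
    reg = np.clip(z * reg_sd + reg_mean, lo, hi)
    values = np.concatenate([np.full(n_pre, pre_period_temp), reg])
    return TemperatureSeries(start, values)


def _simulate_plant(
    first_flowering: dt.date,
    temps: TemperatureSeries,
    model: MaturationModel,
    params: PhenologyParams,
    n_fruits: int,
) -> Optional[list[tuple[dt.date, dt.date]]]:
    """Deterministic (flowering, harvest) pairs for one plant, or None when
    the season ends before every fruit resolves."""
    from .phenology import predict_flowering_dates

    forecast = predict_flowering_dates(first_flowering, temps, params)
    flowering = [first_flowering] + [
        forecast.dates[j] for j in range(2, params.flw_limit + 1) if j in forecast.dates
    ]
    flowering = flowering[:n_fruits]
    if len(flowering) < n_fruits:
        return None
    idx = np.array([temps.index_of(f) for f in flowering])
    h = predict_harvest_indices(temps.values, idx, model.threshold)
    if np.any(h < 0):
        return None
    return [(f, temps.date_at(int(k))) for f, k in zip(flowering, h)]


def back_calculate_first_flowering(
    baseline: TemperatureSeries,
    reference_peak: dt.date,
    model: MaturationModel = MaturationModel(),
    params: PhenologyParams = PhenologyParams(),
    fruits_per_plant: int = 7,
    kernel_sd: float = DEFAULT_KERNEL_SD,
) -> dt.date:
    """First-flowering date whose uncorrected population peak lands closest
    to ``reference_peak`` (earliest date on ties).

    Mirrors the campaign practice of back-calculating each plot's pre-shift
    initial conditions from its predicted harvest peak so that scenarios are
    comparable on the virtual calendar.
    """
    if model.kind != "thermal_threshold":
        raise NotImplementedError("back-calculation supports thermal_threshold truth models")
    best: Optional[tuple[int, dt.date]] = None
    day = baseline.start
    while day <= reference_peak:
        events = _simulate_plant(day, baseline, model, params, fruits_per_plant)
        if events is not None:
            peak = find_peak(
                estimate_distribution([h for _, h in events], kernel_sd)
            ).peak_date
            key = (abs((peak - reference_peak).days), day)
            if best is None or key < best:
                best = key
        day += ONE_DAY
    if best is None:
        raise RuntimeError("no first-flowering date yields a resolvable harvest peak")
    return best[1]


@dataclass(frozen=True)
class ScenarioConfig:
    """One virtual chamber treatment.

    ``flowering_shift`` defaults by kind (CL -7, HT +7, CT 0 days).  Noise
    defaults emulate plant-to-plant variability observed in practice:
    first-flowering dates jittered with SD 2 days, realized maturation with
    SD 1.5 days; set both to zero for a perfect-model run.
    """

    scenario_kind: str = "CT"
    flowering_shift: Optional[int] = None
    n_plants: int = 14
    fruits_per_plant: int = 7
    rng_seed: int = 0
    noise_sd_flowering: float = 2.0
    maturation_noise_sd: float = 1.5
    truth_model: MaturationModel = field(default_factory=MaturationModel)
    reference_peak: dt.date = dt.date(2019, 12, 21)
    virtual_anchor: tuple[dt.date, dt.date] = DEFAULT_ANCHOR

    def __post_init__(self) -> None:
        if self.scenario_kind not in _SHIFT_BY_KIND:
            raise ValueError(f"scenario_kind must be one of {sorted(_SHIFT_BY_KIND)}")
        if self.flowering_shift is None:
            object.__setattr__(self, "flowering_shift", _SHIFT_BY_KIND[self.scenario_kind])
        if abs(self.flowering_shift) > 14:
            raise ValueError("flowering shifts beyond +/-14 days are not supported")
        if self.n_plants < 1:
            raise ValueError("need at least one plant")
        if not 1 <= self.fruits_per_plant <= 7:
            raise ValueError("fruits_per_plant must be in 1..7")

    def perfect_model(self) -> "ScenarioConfig":
        """Copy with all stochastic plant variability removed."""
        return replace(self, noise_sd_flowering=0.0, maturation_noise_sd=0.0)


@dataclass
class _Fruit:
    flowering: Optional[dt.date] = None
    heat: float = 0.0
    harvest: Optional[dt.date] = None  # realized (jittered) harvest date
    reveal: Optional[dt.date] = None  # day the chamber inspection notices it


class ChamberEmulator:
    """Discrete-event virtual chamber advanced one day at a time.

    Each simulated day applies baseline + schedule offset, accumulates every
    plant's inflorescence development and every fruit's post-flowering heat
    sum under the temperature actually in force that day, and reveals events
    (daily visual inspection) once their date is reached.
    """

    def __init__(
        self,
        scenario: ScenarioConfig,
        baseline: Optional[TemperatureSeries] = None,
        params: PhenologyParams = PhenologyParams(),
    ) -> None:
        if scenario.truth_model.kind != "thermal_threshold":
            raise NotImplementedError(
                "the day-by-day chamber emulation supports thermal_threshold "
                "ground-truth maturation"
            )
        self.scenario = scenario
        self.params = params
        self.baseline = baseline if baseline is not None else generate_baseline_temperature(
            scenario.rng_seed
        )
        self.horizon_end = self.baseline.end
        rng = np.random.default_rng(scenario.rng_seed)
        # The flowering shift is expressed in peak space, mirroring the
        # campaign's back-calculation of each plot's pre-shift initial
        # conditions from its predicted harvest peak: the uncorrected peak of
        # a CL/HT population lands |shift| days off the reference date.  (The
        # warm flower-promotion pre-period makes the flowering->peak map
        # nonlinear, so shifting first flowering itself would not do this.)
        desired_peak = scenario.reference_peak + dt.timedelta(days=int(scenario.flowering_shift))
        f0 = back_calculate_first_flowering(
            self.baseline,
            desired_peak,
            scenario.truth_model,
            params,
            scenario.fruits_per_plant,
        )
        self._first_flowering: dict[str, dt.date] = {}
        self._bunch_dev: dict[str, float] = {}
        self._flowers_open: dict[str, int] = {}
        self._fruits: dict[tuple[str, int], _Fruit] = {}
        self._jitter: dict[tuple[str, int], int] = {}
        for p in range(scenario.n_plants):
            pid = f"P{p + 1:02d}"
            noise = (
                int(round(rng.normal(0.0, scenario.noise_sd_flowering)))
                if scenario.noise_sd_flowering > 0
                else 0
            )
            latent = f0 + dt.timedelta(days=noise)
            latent = max(latent, self.baseline.start)
            self._first_flowering[pid] = latent
            self._bunch_dev[pid] = 0.0
            self._flowers_open[pid] = 0
            for j in range(1, scenario.fruits_per_plant + 1):
                self._fruits[(pid, j)] = _Fruit()
                self._jitter[(pid, j)] = (
                    int(round(rng.normal(0.0, scenario.maturation_noise_sd)))
                    if scenario.maturation_noise_sd > 0
                    else 0
                )
        self.current_date = self.baseline.start - ONE_DAY
        self._log_rows: list[dict] = []

    # -- simulation core ---------------------------------------------------

    def _step(self, day: dt.date, temp: float) -> None:
        sc, params = self.scenario, self.params
        events: list[str] = []
        for pid, latent in self._first_flowering.items():
            if day < latent:
                continue
            if self._flowers_open[pid] == 0:
                self._flowers_open[pid] = 1
                if (pid, 1) in self._fruits:
                    self._fruits[(pid, 1)].flowering = day
                    events.append(f"flowering:{pid}/1")
            self._bunch_dev[pid] += bunch_development_increment(temp, params)
            while (
                self._flowers_open[pid] < params.flw_limit
                and self._bunch_dev[pid] >= self._flowers_open[pid]
            ):
                j = self._flowers_open[pid] + 1
                self._flowers_open[pid] = j
                if (pid, j) in self._fruits:
                    self._fruits[(pid, j)].flowering = day
                    events.append(f"flowering:{pid}/{j}")
        threshold = sc.truth_model.threshold
        for key, fruit in self._fruits.items():
            if fruit.flowering is None or fruit.harvest is not None:
                continue
            if day <= fruit.flowering:
                continue  # heat accumulates from the day after flowering
            fruit.heat += temp
            if fruit.heat >= threshold:
                realized = day + dt.timedelta(days=self._jitter[key])
                realized = max(realized, fruit.flowering + ONE_DAY)
                fruit.harvest = realized
                fruit.reveal = max(day, realized)
                events.append(f"harvest:{key[0]}/{key[1]}")
        self._log_rows.append(
            {
                "date": day,
                "applied_temp_c": round(temp, 6),
                "humidity_pct": 70.0,
                "co2_ppm": 400.0,
                "events": ";".join(events),
            }
        )

    def advance_to(self, day: dt.date, schedule: OffsetSchedule) -> list[FruitRecord]:
        """Advance the chamber to ``day`` (inclusive) under ``schedule`` and
        return the fruit records with all observations revealed so far."""
        if day < self.current_date:
            raise ValueError(f"cannot rewind the chamber from {self.current_date} to {day}")
        while self.current_date < day:
            nxt = self.current_date + ONE_DAY
            temp = self.baseline.value_on(nxt) + schedule.offset_on(nxt)
            self._step(nxt, temp)
            self.current_date = nxt
        return self.records()

    def records(self) -> list[FruitRecord]:
        """Snapshot of FruitRecords holding only revealed observations.

        One record per potential flower slot 1..flw_limit and plant: a
        prediction-side simulator always models the full flower complement.
        Slots beyond the scenario's ``fruits_per_plant`` never bloom, which
        reproduces the real failure mode where forecasts count on
        later-blooming flowers the plants do not deliver.
        """
        out: list[FruitRecord] = []
        empty = _Fruit()
        for pid in sorted(self._first_flowering):
            for j in range(1, self.params.flw_limit + 1):
                fruit = self._fruits.get((pid, j), empty)
                flw = fruit.flowering if (
                    fruit.flowering is not None and fruit.flowering <= self.current_date
                ) else None
                harv = fruit.harvest if (
                    fruit.reveal is not None and fruit.reveal <= self.current_date
                ) else None
                out.append(
                    FruitRecord(
                        plant_id=pid,
                        flower_order=j,
                        flowering_observed=flw,
                        harvest_observed=harv if flw is not None else None,
                    )
                )
        return out

    def chamber_log(self) -> pd.DataFrame:
        """Per-day applied temperature, constant humidity/CO2, and events."""
        return pd.DataFrame(
            self._log_rows,
            columns=["date", "applied_temp_c", "humidity_pct", "co2_ppm", "events"],
        )
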