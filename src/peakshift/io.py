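"""CSV / YAML readers and writers.

All on-disk formats are plain text: temperature and fruit-record CSVs with
ISO-8601 dates, scenario/control configuration in YAML, and a JSON run
manifest.  Virtual vs real calendars are distinguished by explicit columns,
never inferred.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .controller import ControlConfig
from .emulator import ScenarioConfig
from .maturation import STAGES, MaturationModel, StageDuration
from .phenology import FruitRecord, PhenologyParams
from .temperature import TemperatureSeries

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_fruit_records",
    "write_fruit_records",
    "read_scenario_file",
    "write_manifest",
]

FRUIT_COLUMNS = [
    "plant_id",
    "flower_order",
    "flowering_observed",
    "flowering_predicted",
    "harvest_observed",
    "harvest_predicted",
]


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(str(text))


def read_temperature_csv(path: str | Path) -> TemperatureSeries:
    """Read a `date,temp_c` CSV into a contiguous TemperatureSeries.

    Gaps and duplicate dates are hard errors naming the offending dates.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["date", "temp_c"]:
        raise ValueError(f"{path}: expected header 'date,temp_c', got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: empty temperature file")
    dates = [_parse_date(d) for d in df["date"]]
    dupes = sorted({d for d in dates if dates.count(d) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated dates {[d.isoformat() for d in dupes]}")
    order = np.argsort(dates)
    dates = [dates[i] for i in order]
    values = df["temp_c"].to_numpy(float)[order]
    expected = {dates[0] + dt.timedelta(days=i) for i in range((dates[-1] - dates[0]).days + 1)}
    missing = sorted(expected - set(dates))
    if missing:
        raise ValueError(f"{path}: missing dates {[d.isoformat() for d in missing]}")
    return TemperatureSeries(dates[0], values)


def write_temperature_csv(series: TemperatureSeries, path: str | Path) -> None:
    pd.DataFrame({"date": [d.isoformat() for d in series.dates()], "temp_c": series.values}).to_csv(
        path, index=False
    )


def read_fruit_records(
    path: str | Path, flw_limit: int = PhenologyParams().flw_limit
) -> list[FruitRecord]:
    """Read tagged-fruit records; flower orders beyond ``flw_limit`` are
    rejected (those flowers are removed in cultivation, never simulated)."""
    df = pd.read_csv(path, dtype={"plant_id": str})
    if list(df.columns) != FRUIT_COLUMNS:
        raise ValueError(f"{path}: expected header {','.join(FRUIT_COLUMNS)}")
    records = []
    for _, row in df.iterrows():
        order = int(row["flower_order"])
        if order > flw_limit:
            raise ValueError(
                f"{path}: flower_order {order} exceeds the {flw_limit}-flower limit"
            )
        dates = {
            col: (None if pd.isna(row[col]) or row[col] == "" else _parse_date(row[col]))
            for col in FRUIT_COLUMNS[2:]
        }
        records.append(FruitRecord(plant_id=str(row["plant_id"]), flower_order=order, **dates))
    return records


def write_fruit_records(records: Iterable[FruitRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "plant_id": r.plant_id,
                "flower_order": r.flower_order,
                "flowering_observed": r.flowering_observed.isoformat() if r.flowering_observed else "",
                "flowering_predicted": r.flowering_predicted.isoformat() if r.flowering_predicted else "",
                "harvest_observed": r.harvest_observed.isoformat() if r.harvest_observed else "",
                "harvest_predicted": r.harvest_predicted.isoformat() if r.harvest_predicted else "",
            }
        )
    pd.DataFrame(rows, columns=FRUIT_COLUMNS).to_csv(path, index=False)


def _model_from_config(cfg: dict) -> MaturationModel:
    kind = cfg.get("kind", "thermal_threshold")
    if kind == "thermal_threshold":
        return MaturationModel.thermal_threshold(float(cfg.get("threshold", 600.0)))
    if kind == "stage_regression":
        stages = cfg.get("stages", {})
        if set(stages) != set(STAGES):
            raise ValueError(f"stage_regression config must define stages {STAGES}")
        return MaturationModel.stage_regression(
            {
                s: StageDuration(spec["family"], tuple(spec["coefficients"]))
                for s, spec in stages.items()
            }
        )
    raise ValueError(f"unknown maturation model kind {kind!r}")


def read_scenario_file(
    path: str | Path,
) -> tuple[ScenarioConfig, ControlConfig, MaturationModel, PhenologyParams, float]:
    """Parse a YAML scenario file.

    Top-level blocks (all optional except ``scenario``): ``scenario``
    (kind/shift/population/seeds/noise), ``control`` (target, search grid,
    update calendar), ``model`` (maturation model; a ``stages`` block with
    per-stage ``family`` and ``coefficients`` selects stage regression),
    ``phenology`` (ct_ff, flw_limit) and ``distribution`` (kernel_sd).
    Returns (scenario, control, model, phenology params, kernel sd).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    sc = cfg.get("scenario", {})
    model = _model_from_config(cfg.get("model", {}))
    scenario = ScenarioConfig(
        scenario_kind=sc.get("kind", "CT"),
        flowering_shift=sc.get("flowering_shift"),
        n_plants=int(sc.get("n_plants", 14)),
        fruits_per_plant=int(sc.get("fruits_per_plant", 7)),
        rng_seed=int(sc.get("seed", 0)),
        noise_sd_flowering=float(sc.get("noise_sd_flowering", 2.0)),
        maturation_noise_sd=float(sc.get("maturation_noise_sd", 1.5)),
        truth_model=model,
    )
    cc = cfg.get("control", {})
    defaults = ControlConfig()
    control = ControlConfig(
        target_date=_parse_date(cc["target_date"]) if "target_date" in cc else defaults.target_date,
        search_min=float(cc.get("search_min", defaults.search_min)),
        search_max=float(cc.get("search_max", defaults.search_max)),
        search_step=float(cc.get("search_step", defaults.search_step)),
        intervention_start=(
            _parse_date(cc["intervention_start"])
            if "intervention_start" in cc
            else defaults.intervention_start
        ),
        update_dates=(
            tuple(_parse_date(d) for d in cc["update_dates"])
            if "update_dates" in cc
            else defaults.update_dates
        ),
        horizon_end=_parse_date(cc["horizon_end"]) if "horizon_end" in cc else defaults.horizon_end,
        stop_after_target=bool(cc.get("stop_after_target", False)),
    )
    ph = cfg.get("phenology", {})
    params = PhenologyParams(
        ct_ff=float(ph.get("ct_ff", 252.1)), flw_limit=int(ph.get("flw_limit", 7))
    )
    kernel_sd = float(cfg.get("distribution", {}).get("kernel_sd", 14.34))
    return scenario, control, model, params, kernel_sd


def write_manifest(out_dir: str | Path, config_echo: dict, seed: Optional[int]) -> Path:
    """Write a reproducibility manifest (config echo, seed, versions)."""
    import peakshift

    out = Path(out_dir) / "manifest.json"
    payload = {
        "peakshift_version": peakshift.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config": config_echo,
    }
    out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return out
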