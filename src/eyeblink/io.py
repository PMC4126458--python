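"""File dialects: event trains, session logs, calibration reports, configs.

Everything is plain text (CSV/JSON/YAML) so runs are diffable and portable:

* event trains -- CSV with columns ``channel,time_s`` (several channels may
  share a file) or a JSON document with the grid and per-channel time lists;
* session logs -- one CSV row per trial plus a JSON summary with the seed,
  parameters and recalibration history;
* configuration -- a single YAML/JSON document with ``model``, ``latencies``
  and ``protocol`` sections; every default is overridable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .grid import EventTrain, TimeGrid
from .model import LatencyBudget, ModelParams, SessionLog, TraceParams

__all__ = [
    "write_trains_csv",
    "read_trains_csv",
    "write_trains_json",
    "read_trains_json",
    "write_session_log",
    "write_calibration_report",
    "load_config",
    "dump_config",
    "params_from_config",
    "latencies_from_config",
]


def write_trains_csv(path, trains: list[EventTrain]) -> None:
    rows = [{"channel": tr.channel, "time_s": t} for tr in trains for t in tr.times]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)


def read_trains_csv(path, grid: TimeGrid) -> dict[str, EventTrain]:
    df = pd.read_csv(path)
    if not {"channel", "time_s"} <= set(df.columns):
        raise InputError("event-train CSV needs 'channel' and 'time_s' columns")
    return {
        ch: EventTrain.from_times(ch, sub["time_s"].to_numpy(), grid)
        for ch, sub in df.groupby("channel")
    }


def write_trains_json(path, trains: list[EventTrain]) -> None:
    grid = trains[0].grid if trains else TimeGrid()
    doc = {
        "dt": grid.dt,
        "horizon": grid.horizon,
        "channels": {tr.channel: [float(t) for t in tr.times] for tr in trains},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_trains_json(path) -> dict[str, EventTrain]:
    doc = json.loads(Path(path).read_text())
    grid = TimeGrid(float(doc["dt"]), int(doc["horizon"]))
    return {ch: EventTrain.from_times(ch, times, grid) for ch, times in doc["channels"].items()}


def write_session_log(prefix, log: SessionLog) -> tuple[Path, Path]:
    """Write ``<prefix>.trials.csv`` and ``<prefix>.summary.json``."""
    prefix = Path(prefix)
    trials_path = Path(str(prefix) + ".trials.csv")
    log.trials.to_csv(trials_path, index_label="trial")
    summary = {
        "seed": log.seed,
        "n_trials": log.n_trials,
        "w_final": log.w_final,
        "n_cr": len(log.cr_events),
        "params": dataclasses.asdict(log.params),
        "recalibrations": [
            {"time_s": t, "io_far_hz": f, "delta_p": p, "delta_d": d}
            for (t, f, p, d) in log.recalibrations
        ],
    }
    summary_path = Path(str(prefix) + ".summary.json")
    summary_path.write_text(json.dumps(summary, indent=1, default=_jsonable))
    return trials_path, summary_path


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def write_calibration_report(path, result, kappa: float | None = None) -> None:
    doc = {
        "delta_p": result.delta_p,
        "delta_d": result.delta_d,
        "clamped": result.clamped,
        "residuals": list(map(float, result.residuals)),
        "summaries": [dataclasses.asdict(s) for s in result.summaries],
        "constraints": dataclasses.asdict(result.constraints),
        "operating_point": result.operating_point,
    }
    if kappa is not None:
        doc["kappa_s_per_trial"] = kappa
    Path(path).write_text(json.dumps(doc, indent=1, default=_jsonable))


# ---------------------------------------------------------------------------
# configuration documents


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def dump_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def params_from_config(config: dict) -> ModelParams:
    model = dict(config.get("model", {}))
    trace = TraceParams(**model.pop("trace", {}))
    if "w_bounds" in model:
        model["w_bounds"] = tuple(model["w_bounds"])
    return ModelParams(trace=trace, **model)


def latencies_from_config(config: dict) -> LatencyBudget:
    return LatencyBudget(**config.get("latencies", {}))
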