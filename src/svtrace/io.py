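"""Delimited-text I/O for traces, truth tables, event tables and reports.

Trace tables are CSV with a ``time_s`` column plus one column per bouton; the
sampling rate is inferred from the time stamps.  Event tables carry one row
per stimulus, including failures.  Reports and configs are JSON / YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .detect import DetectionResult, FusionEvent
from .simulate import RetrievalFractionDist, SimulationConfig
from .trace import FluorescenceTrace

__all__ = [
    "write_traces",
    "read_traces",
    "write_events",
    "read_events",
    "write_report",
    "load_config",
    "dump_config",
    "events_to_frame",
]


def write_traces(path: str | Path, traces: Sequence[FluorescenceTrace]) -> None:
    rates = {tr.sampling_rate_hz for tr in traces}
    if len(rates) != 1:
        raise ValueError("all traces in one table must share a sampling rate")
    n = {len(tr) for tr in traces}
    if len(n) != 1:
        raise ValueError("all traces in one table must have equal length")
    df = pd.DataFrame({"time_s": traces[0].times()})
    for tr in traces:
        df[tr.bouton_id] = tr.samples
    df.to_csv(path, index=False, float_format="%.17g")


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    """Read a trace table; the sampling rate is inferred from ``time_s``."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed trace table {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValueError(f"trace table {path} is missing the required 'time_s' column")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric cells in columns {bad} of {path}")
    if df.isna().any().any():
        raise ValueError(f"missing values (ragged rows?) in trace table {path}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("trace table needs at least two rows")
    dt = np.median(np.diff(t))
    if dt <= 0:
        raise ValueError("time stamps must be increasing")
    rate = 1.0 / dt
    # snap to the common acquisition rates when within round-off
    for known in (10.0, 40.0):
        if abs(rate - known) / known < 1e-3:
            rate = known
    return [
        FluorescenceTrace(df[c].to_numpy(), rate, t0_s=float(t[0]), bouton_id=str(c))
        for c in df.columns
        if c != "time_s"
    ]


def events_to_frame(
    results: dict[str, DetectionResult], stimulus_times_s: Sequence[float]
) -> pd.DataFrame:
    """One row per stimulus per bouton, successes and failures alike."""
    rows = []
    for bouton, res in results.items():
        by_stim: dict[int, FusionEvent] = {ev.stimulus_index: ev for ev in res.events}
        mv = {ev.stimulus_index: ev for ev in res.multivesicular}
        for idx, stim in enumerate(stimulus_times_s):
            base: dict[str, Any] = {
                "bouton_id": bouton,
                "stimulus_index": idx,
                "stimulus_time_s": stim,
                "detected": idx in by_stim,
                "multivesicular": idx in mv,
                "skipped": idx in res.skipped_stimuli,
            }
            ev = by_stim.get(idx)
            if ev is not None:
                base.update(
                    onset_time_s=ev.onset_time_s,
                    peak_amplitude=ev.peak_amplitude,
                    baseline_mean=ev.baseline_mean,
                    baseline_sd=ev.baseline_sd,
                    dwell_time_s=ev.dwell_time_s,
                    censored=ev.censored,
                    decay_onset_time_s=ev.decay_onset_time_s,
                    retrieval_fraction=ev.retrieval_fraction,
                    mode=ev.mode,
                    retrieval_class=ev.retrieval_class,
                )
            rows.append(base)
    return pd.DataFrame(rows)


def write_events(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path: str | Path, report: dict[str, Any]) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def dump_config(path: str | Path, config: SimulationConfig) -> None:
    d = dataclasses.asdict(config)
    d.pop("condition", None)
    yaml.safe_dump(d, Path(path).open("w"))


def load_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "retrieval_fraction_dist" in raw and isinstance(raw["retrieval_fraction_dist"], dict):
        rfd = raw["retrieval_fraction_dist"]
        for key in ("weights", "partial_range", "excess_range"):
            if key in rfd:
                rfd[key] = tuple(rfd[key])
        raw["retrieval_fraction_dist"] = RetrievalFractionDist(**rfd)
    if "mode_weights" in raw:
        raw["mode_weights"] = tuple(raw["mode_weights"])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg
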