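"""CSV schemas, timestamp handling and run configuration.

Internally the pipeline works in integer minutes from subject start; on disk
timestamps are ISO 8601 UTC relative to a fixed epoch, blanks are empty
cells and validity flags are 0/1.  All round-trips are lossless for finite
values and blanks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import PeakConfig, SmoothingConfig
from .preprocess import QualityConfig, RangeBounds, Section
from .predictor import AlarmSummary, PredictorConfig, PredictorTrace
from .series import (
    CONDITION_FLAGS,
    Conditions,
    PressureSeries,
    SubjectProfile,
    VitalSeries,
)

EPOCH = pd.Timestamp("2023-01-01T00:00:00Z")

VITALS_COLUMNS = ["timestamp", "spo2", "spo2_valid", "hr", "hr_valid", "temp", "temp_valid"]


def minutes_to_iso(minutes) -> str:
    return (EPOCH + pd.Timedelta(minutes=int(minutes))).strftime("%Y-%m-%dT%H:%M:%SZ")


def iso_to_minutes(stamp: str) -> int:
    ts = pd.Timestamp(stamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    delta = (ts - EPOCH).total_seconds()
    return int(delta // 60)


def _flag_col(flags: np.ndarray) -> np.ndarray:
    return flags.astype(int)


def write_vitals(series: VitalSeries, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [minutes_to_iso(m) for m in series.t],
            "spo2": series.spo2,
            "spo2_valid": _flag_col(series.spo2_valid),
            "hr": series.hr,
            "hr_valid": _flag_col(series.hr_valid),
            "temp": series.temp,
            "temp_valid": _flag_col(series.temp_valid),
        }
    )
    df.to_csv(path, index=False)


def read_vitals(path) -> VitalSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        e = np.empty(0)
        return VitalSeries(t=np.empty(0, dtype=np.int64), spo2=e, hr=e.copy(), temp=e.copy())
    parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = parsed.isna()
    if bad.any():
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: malformed timestamp at line {int(np.flatnonzero(bad)[0]) + 2}")
    t = ((parsed - EPOCH).dt.total_seconds() // 60).astype(np.int64).to_numpy()
    interval = int(t[1] - t[0]) if t.size > 1 else 1

    def chan(name: str):
        vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        flags = pd.to_numeric(df[f"{name}_valid"], errors="coerce").fillna(0).to_numpy() != 0
        return vals, flags & ~np.isnan(vals)

    spo2, spo2_v = chan("spo2")
    hr, hr_v = chan("hr")
    temp, temp_v = chan("temp")
    return VitalSeries(
        t=t, spo2=spo2, hr=hr, temp=temp,
        spo2_valid=spo2_v, hr_valid=hr_v, temp_valid=temp_v, interval=interval,
    )


def _grid_columns(rows: int, cols: int) -> list[str]:
    return [f"r{r}c{c}" for r in range(rows) for c in range(cols)]


def write_pressure(series: PressureSeries, path) -> None:
    rows, cols = series.grid_shape
    flat = series.grid.reshape(series.n, rows * cols)
    df = pd.DataFrame(flat, columns=_grid_columns(rows, cols))
    df.insert(0, "timestamp", [minutes_to_iso(m) for m in series.t])
    df.to_csv(path, index=False)


def read_pressure(path) -> PressureSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: missing 'timestamp' column")
    grid_cols = [c for c in df.columns if c != "timestamp"]
    rows = 1 + max(int(c[1 : c.index("c")]) for c in grid_cols)
    cols = 1 + max(int(c[c.index("c") + 1 :]) for c in grid_cols)
    expected = _grid_columns(rows, cols)
    if sorted(grid_cols) != sorted(expected):
        raise ValueError(f"{path}: grid columns do not form a complete {rows}x{cols} grid")
    parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        raise ValueError(f"{path}: malformed timestamp")
    t = ((parsed - EPOCH).dt.total_seconds() // 60).astype(np.int64).to_numpy()
    grid = df[expected].to_numpy(dtype=float).reshape(len(df), rows, cols)
    interval = int(t[1] - t[0]) if t.size > 1 else 5
    return PressureSeries(t=t, grid=grid, interval=interval)


def write_subjects(profiles: list[SubjectProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "group": p.group,
            "age": p.age,
            "height": p.height,
            "weight": p.weight,
        }
        row.update({f: int(v) for f, v in p.conditions.as_dict().items()})
        row["diagnosis_events"] = ";".join(f"{t}:{r}" for t, r in p.diagnosis_events)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subjects(path) -> list[SubjectProfile]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        events = []
        raw = str(row.get("diagnosis_events", "") or "")
        for item in filter(None, raw.split(";")):
            t_str, result = item.split(":")
            events.append((int(t_str), result))
        out.append(
            SubjectProfile(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                height=float(row["height"]),
                weight=float(row["weight"]),
                conditions=Conditions(**{f: bool(int(row[f])) for f in CONDITION_FLAGS}),
                diagnosis_events=events,
            )
        )
    return out


def write_sections(sections: list[Section], path) -> None:
    pd.DataFrame(
        [
            {"subject_id": s.subject_id, "t_start": s.t_start, "t_end": s.t_end, "length": s.length}
            for s in sections
        ],
        columns=["subject_id", "t_start", "t_end", "length"],
    ).to_csv(path, index=False)


def write_events(events, path) -> None:
    pd.DataFrame(
        [
            {
                "t_peak": e.t_peak,
                "direction": e.direction,
                "prominence": e.prominence,
                "width": e.width,
                "cluster": "" if e.cluster_label is None else e.cluster_label,
            }
            for e in events
        ],
        columns=["t_peak", "direction", "prominence", "width", "cluster"],
    ).to_csv(path, index=False)


def write_sta(entry, path) -> None:
    pd.DataFrame(
        {"rel_time": entry.rel_time, "mean_delta_temp": entry.mean_delta_temp, "n": entry.n}
    ).to_csv(path, index=False)


def write_predictor_trace(trace: PredictorTrace, path) -> None:
    pd.DataFrame(
        {
            "t": trace.t,
            "rolling_mean": trace.rolling_mean,
            "expanding_mean": trace.expanding_mean,
            "diff": trace.diff,
            "state": trace.state,
        }
    ).to_csv(path, index=False)


def write_alarms(summaries: list[AlarmSummary], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "n_alarms": s.n_alarms,
                "intervals": ";".join(f"{a}-{b}" for a, b in s.alarm_intervals),
            }
            for s in summaries
        ],
        columns=["subject_id", "n_alarms", "intervals"],
    ).to_csv(path, index=False)


def write_comparisons(comparisons, path) -> None:
    pd.DataFrame(
        [
            {
                "channel": c.channel,
                "stratifier": c.stratifier,
                "mean_a": c.mean_a,
                "sd_a": c.sd_a,
                "mean_b": c.mean_b,
                "sd_b": c.sd_b,
                "t": c.welch_t,
                "df": c.welch_df,
                "p": c.p_value,
                "significant": int(c.significant),
            }
            for c in comparisons
        ],
        columns=["channel", "stratifier", "mean_a", "sd_a", "mean_b", "sd_b", "t", "df", "p", "significant"],
    ).to_csv(path, index=False)


def write_foot_summary(summary, path) -> None:
    rows = [
        {"group": g, "region": r, "mean_load": v["mean_load"], "peak_load": v["peak_load"]}
        for g, regions in summary.items()
        for r, v in regions.items()
    ]
    pd.DataFrame(rows, columns=["group", "region", "mean_load", "peak_load"]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration


@dataclass
class FootStageConfig:
    enabled: bool = False
    n_orthopedic: int = 3
    n_regular: int = 3
    n_control: int = 3
    duration: int = 600


@dataclass
class RunConfig:
    """Umbrella configuration of the end-to-end pipeline."""

    n_patients: int = 2
    n_controls: int = 1
    duration: int = 1440
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    generator: dict = field(default_factory=dict)
    quality: QualityConfig = field(default_factory=QualityConfig)
    bounds: RangeBounds = field(default_factory=RangeBounds)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    event_direction: str = "both"
    stratify: str | None = None
    foot: FootStageConfig = field(default_factory=FootStageConfig)


_NESTED = {
    "quality": QualityConfig,
    "bounds": RangeBounds,
    "smoothing": SmoothingConfig,
    "peaks": PeakConfig,
    "predictor": PredictorConfig,
    "foot": FootStageConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = _build(_NESTED[key], value)
        else:
            kwargs[key] = value
    return _build(RunConfig, kwargs)


def config_hash(config: RunConfig) -> str:
    """Deterministic digest of a run configuration (stamped on artifacts)."""

    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return str(obj)

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
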