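"""The SpO2 early-warning predictor.

Per minute, the difference between the trailing one-hour rolling mean of
SpO2 (computed only when at least 90% of the window's samples are valid)
and the expanding mean of all patient data available at that time is
evaluated; the state is ``warn`` when the difference falls to or below the
threshold (default -3 percentage points), ``normal`` otherwise, and
``undefined`` wherever the difference cannot be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import CohortDataset, VitalSeries

_EPS = 1e-9


@dataclass(frozen=True)
class PredictorConfig:
    """Window length, validity gate, warning threshold, expanding-mean
    warm-up and the alarm merge gap (all minutes / fractions / points)."""

    window: int = 60
    min_valid_frac: float = 0.9
    thres: float = -3.0
    warmup: int = 120
    merge_gap: int = 60

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0.0 < self.min_valid_frac <= 1.0:
            raise ValueError("min_valid_frac must lie in (0, 1]")
        if self.warmup < 0:
            raise ValueError("warmup must be non-negative")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")


@dataclass
class PredictorTrace:
    """Per-minute predictor quantities; absent values are NaN and map to the
    ``undefined`` state."""

    t: np.ndarray
    rolling_mean: np.ndarray
    expanding_mean: np.ndarray
    diff: np.ndarray
    state: np.ndarray  # '<U9': "warn" | "normal" | "undefined"


@dataclass
class AlarmSummary:
    """Merged warning intervals of one subject (half-open minutes)."""

    subject_id: str
    alarm_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_alarms(self) -> int:
        return len(self.alarm_intervals)


def _valid_spo2(series: VitalSeries) -> tuple[np.ndarray, np.ndarray]:
    valid = series.spo2_valid & ~np.isnan(series.spo2)
    vals = np.where(valid, series.spo2, 0.0)
    return vals, valid


def rolling_mean_spo2(series: VitalSeries, config: PredictorConfig | None = None) -> np.ndarray:
    """Right-aligned rolling mean of valid SpO2 over ``window`` minutes
    ending at (and including) each t.

    NaN where the window underruns the series start or where fewer than
    ``min_valid_frac`` of its samples are valid.
    """
    config = config or PredictorConfig()
    if config.window % series.interval != 0:
        raise ValueError("series interval must divide the predictor window")
    w = config.window // series.interval
    vals, valid = _valid_spo2(series)
    n = series.n
    out = np.full(n, np.nan)
    if n < w:
        return out
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    idx = np.arange(w - 1, n)
    cnt = ccnt[idx + 1] - ccnt[idx + 1 - w]
    total = csum[idx + 1] - csum[idx + 1 - w]
    ok = (cnt + _EPS >= config.min_valid_frac * w) & (cnt > 0)
    out[idx[ok]] = total[ok] / cnt[ok]
    return out


def expanding_mean_spo2(
    series: VitalSeries, config: PredictorConfig | None = None, t: int | None = None
):
    """Expanding mean of all valid SpO2 from series start up to each t.

    NaN while no valid sample has been seen or before ``warmup`` minutes
    have elapsed.  With ``t`` given, returns the scalar value at that grid
    minute.
    """
    config = config or PredictorConfig()
    vals, valid = _valid_spo2(series)
    csum = np.cumsum(vals)
    ccnt = np.cumsum(valid.astype(np.int64))
    out = np.full(series.n, np.nan)
    have = ccnt > 0
    out[have] = csum[have] / ccnt[have]
    if series.n:
        out[(series.t - series.t[0]) < config.warmup] = np.nan
    if t is None:
        return out
    idx = np.flatnonzero(series.t == t)
    if idx.size == 0:
        raise ValueError(f"t={t} is not on the series grid")
    return float(out[idx[0]])


def diff_and_state(series: VitalSeries, config: PredictorConfig | None = None) -> PredictorTrace:
    """Evaluate the predictor: diff = rolling - expanding mean; state is
    ``warn`` iff diff <= thres (inclusive), ``undefined`` where diff is
    absent."""
    config = config or PredictorConfig()
    rolling = rolling_mean_spo2(series, config)
    expanding = expanding_mean_spo2(series, config)
    diff = rolling - expanding
    state = np.full(series.n, "undefined", dtype="<U9")
    defined = ~np.isnan(diff)
    state[defined & (diff <= config.thres)] = "warn"
    state[defined & (diff > config.thres)] = "normal"
    return PredictorTrace(
        t=series.t.copy(), rolling_mean=rolling, expanding_mean=expanding, diff=diff, state=state
    )


def alarm_events(
    trace: PredictorTrace, config: PredictorConfig | None = None, subject_id: str = ""
) -> AlarmSummary:
    """Summarise warn states into alarm intervals.

    Maximal warn runs separated by at most ``merge_gap`` minutes of non-warn
    states merge into one alarm; the merged intervals are disjoint, ordered
    and separated by more than the gap.
    """
    config = config or PredictorConfig()
    warn = trace.state == "warn"
    if trace.t.size == 0 or not warn.any():
        return AlarmSummary(subject_id=subject_id)
    interval = int(trace.t[1] - trace.t[0]) if trace.t.size > 1 else 1
    runs: list[tuple[int, int]] = []
    i = 0
    n = warn.size
    while i < n:
        if not warn[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and warn[j + 1]:
            j += 1
        runs.append((int(trace.t[i]), int(trace.t[j]) + interval))
        i = j + 1
    merged = [runs[0]]
    for start, end in runs[1:]:
        if start - merged[-1][1] <= config.merge_gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return AlarmSummary(subject_id=subject_id, alarm_intervals=merged)


def evaluate_cohort(
    dataset: CohortDataset, config: PredictorConfig | None = None
) -> list[AlarmSummary]:
    """One alarm summary per (already preprocessed) subject; deterministic
    and invariant to subject ordering."""
    config = config or PredictorConfig()
    out = []
    for profile, vitals, _pressure in dataset:
        trace = diff_and_state(vitals, config)
        out.append(alarm_events(trace, config, subject_id=profile.subject_id))
    return out
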