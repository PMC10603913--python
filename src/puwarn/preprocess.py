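"""Stream preprocessing: uniform gridding, out-of-range removal, capped
forward fill, the per-timestamp data-quality factor and quality-thresholded
segmentation into relevant sections.

The pipeline order is fixed: grid -> range-delete -> fill -> quality ->
segment.  Filled values count as valid for the quality factor (and for the
downstream predictor gate); they exist to bridge short dropouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import VITAL_CHANNELS, VitalSeries


@dataclass(frozen=True)
class RangeBounds:
    """Inclusive physical-range bounds per channel.

    The bounds themselves are a configuration choice (adult physiological
    plausibility): SpO2 70-100 %, HR 30-220 bpm, skin temperature 25-45 C.
    """

    spo2: tuple[float, float] = (70.0, 100.0)
    hr: tuple[float, float] = (30.0, 220.0)
    temp: tuple[float, float] = (25.0, 45.0)

    def __post_init__(self) -> None:
        for ch in VITAL_CHANNELS:
            lo, hi = getattr(self, ch)
            if not lo < hi:
                raise ValueError(f"{ch}: low bound must be below high bound")

    def bounds(self, channel: str) -> tuple[float, float]:
        return getattr(self, channel)


@dataclass(frozen=True)
class QualityConfig:
    """Forward-fill cap, quality threshold (strict >) and minimum section
    length, all in minutes / fractions."""

    ffill_max: int = 5
    quality_threshold: float = 2.0 / 3.0
    min_section_length: int = 60

    def __post_init__(self) -> None:
        if self.ffill_max < 0:
            raise ValueError("ffill_max must be non-negative")
        if not 0.0 <= self.quality_threshold <= 1.0:
            raise ValueError("quality_threshold must lie in [0, 1]")
        if self.min_section_length < 0:
            raise ValueError("min_section_length must be non-negative")


@dataclass(frozen=True)
class Section:
    """A relevant half-open data section [t_start, t_end) of one subject."""

    t_start: int
    t_end: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def length(self) -> int:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SectionStats:
    count: int
    mean_length: float | None = None
    median_length: float | None = None


def normalize_timeline(records, interval: int = 1) -> VitalSeries:
    """Regrid raw records onto a complete equally spaced timeline.

    ``records`` is a DataFrame (or anything DataFrame-constructible) with a
    ``t`` column of minutes or a ``timestamp`` column of ISO 8601 strings,
    plus any of the channel columns ``spo2/hr/temp`` and optional
    ``<ch>_valid`` flags.  Missing timestamps become blank records flagged
    invalid; duplicate timestamps collapse to the last record; timestamps
    off the grid are floored onto it.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    df = pd.DataFrame(records)
    if df.empty:
        empty = np.empty(0)
        return VitalSeries(t=np.empty(0, dtype=np.int64), spo2=empty, hr=empty.copy(),
                           temp=empty.copy(), interval=interval)

    if "t" in df.columns:
        minutes = pd.to_numeric(df["t"], errors="coerce")
        bad = minutes.isna()
        if bad.any():
            raise ValueError(f"unparsable time value in row {int(np.flatnonzero(bad)[0])}")
        minutes = minutes.astype(np.int64)
    elif "timestamp" in df.columns:
        from . import io as _io

        parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
        bad = parsed.isna()
        if bad.any():
            raise ValueError(f"unparsable timestamp in row {int(np.flatnonzero(bad)[0])}")
        minutes = ((parsed - _io.EPOCH).dt.total_seconds() // 60).astype(np.int64)
    else:
        raise ValueError("records need a 't' or 'timestamp' column")

    t0 = int(minutes.min())
    snapped = t0 + ((minutes - t0) // interval) * interval
    grid = np.arange(t0, int(snapped.max()) + interval, interval, dtype=np.int64)
    pos = ((snapped - t0) // interval).to_numpy()

    n = grid.size
    out_vals = {ch: np.full(n, np.nan) for ch in VITAL_CHANNELS}
    out_valid = {ch: np.zeros(n, dtype=bool) for ch in VITAL_CHANNELS}
    for ch in VITAL_CHANNELS:
        if ch in df.columns:
            vals = pd.to_numeric(df[ch], errors="coerce").to_numpy(dtype=float)
        else:
            vals = np.full(len(df), np.nan)
        if f"{ch}_valid" in df.columns:
            valid = df[f"{ch}_valid"].fillna(0).astype(float).to_numpy() != 0
        else:
            valid = ~np.isnan(vals)
        # duplicates: last record wins
        out_vals[ch][pos] = vals
        out_valid[ch][pos] = valid & ~np.isnan(vals)

    return VitalSeries(
        t=grid,
        spo2=out_vals["spo2"],
        hr=out_vals["hr"],
        temp=out_vals["temp"],
        spo2_valid=out_valid["spo2"],
        hr_valid=out_valid["hr"],
        temp_valid=out_valid["temp"],
        interval=interval,
    )


def remove_out_of_range(series: VitalSeries, bounds: RangeBounds | None = None) -> VitalSeries:
    """Blank every reading outside its channel's physical range.

    Out-of-range values become NaN and invalid; in-range values are
    untouched.  Channels are handled independently.  Idempotent.
    """
    bounds = bounds or RangeBounds()
    out = series.copy()
    for ch in VITAL_CHANNELS:
        lo, hi = bounds.bounds(ch)
        vals = out.values(ch)
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(vals) & ((vals < lo) | (vals > hi))
        vals[bad] = np.nan
        out.valid(ch)[bad] = False
        out.filled(ch)[bad] = False
    return out


def forward_fill(series: VitalSeries, ffill_max: int = 5) -> VitalSeries:
    """Carry the last original valid value over blank runs, capped at
    ``ffill_max`` minutes.

    Filled records are flagged valid and marked filled.  Runs longer than the
    cap stay blank beyond it; leading blanks are never filled.  Values that
    were themselves filled never serve as a fill source, which makes the
    operation idempotent.
    """
    if ffill_max < 0:
        raise ValueError("ffill_max must be non-negative")
    out = series.copy()
    cap = ffill_max // out.interval
    if cap == 0 or out.n == 0:
        return out
    for ch in VITAL_CHANNELS:
        vals = out.values(ch)
        valid = out.valid(ch)
        filled = out.filled(ch)
        source = pd.Series(np.where(valid & ~filled, vals, np.nan))
        carried = source.ffill(limit=cap).to_numpy()
        target = ~valid & ~np.isnan(carried)
        vals[target] = carried[target]
        valid[target] = True
        filled[target] = True
    return out


def quality_factor(series: VitalSeries, t: int | None = None):
    """Fraction of valid vital channels per timestamp (in {0, 1/3, 2/3, 1}).

    With ``t`` given, returns the scalar factor at that grid minute.
    """
    counts = (
        series.spo2_valid.astype(int)
        + series.hr_valid.astype(int)
        + series.temp_valid.astype(int)
    )
    qf = counts / len(VITAL_CHANNELS)
    if t is None:
        return qf
    idx = np.flatnonzero(series.t == t)
    if idx.size == 0:
        raise ValueError(f"t={t} is not on the series grid")
    return float(qf[idx[0]])


def segment_sections(
    series: VitalSeries, config: QualityConfig | None = None, subject_id: str = ""
) -> list[Section]:
    """Split the series into maximal runs with quality factor strictly above
    the threshold; runs shorter than ``min_section_length`` are discarded."""
    config = config or QualityConfig()
    if series.n == 0:
        return []
    good = quality_factor(series) > config.quality_threshold
    sections: list[Section] = []
    i = 0
    n = series.n
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and good[j + 1]:
            j += 1
        t_start = int(series.t[i])
        t_end = int(series.t[j]) + series.interval
        if t_end - t_start >= config.min_section_length:
            sections.append(Section(t_start=t_start, t_end=t_end, subject_id=subject_id))
        i = j + 1
    return sections


def section_stats(sections: list[Section]) -> SectionStats:
    """Mean and median of section lengths; stats are absent for no sections."""
    if not sections:
        return SectionStats(count=0)
    lengths = np.array([s.length for s in sections], dtype=float)
    return SectionStats(
        count=len(sections),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
    )


def preprocess_series(
    series: VitalSeries,
    bounds: RangeBounds | None = None,
    config: QualityConfig | None = None,
) -> VitalSeries:
    """Apply the fixed pipeline order: range-delete then capped forward fill.

    The input is assumed to be gridded already (see
    :func:`normalize_timeline` for raw records).
    """
    config = config or QualityConfig()
    return forward_fill(remove_out_of_range(series, bounds), config.ffill_max)
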