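"""Pressure-event analysis: low-pass smoothing, z-scoring, peak-based event
detection, event-window extraction, duration clustering and spike-triggered
averaging of the skin-temperature response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.cluster import KMeans

from .series import PressureSeries


@dataclass(frozen=True)
class SmoothingConfig:
    """Zero-phase low-pass Butterworth filter.

    Defaults (order 2, cutoff 1/30 cycles per minute) preserve events of
    roughly 20 minutes and longer while removing minute-scale jitter.
    """

    order: int = 2
    cutoff: float = 1.0 / 30.0  # cycles per minute
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class PeakConfig:
    """Peak filters: minimal event spacing, minimal prominence (in the units
    of the detected series, z-units after standardisation) and bounds on the
    width at half prominence, interpreted as the event-duration proxy."""

    min_distance: int = 10  # minutes
    min_prominence: float = 1.0
    width_bounds: tuple[float, float] = (5.0, 120.0)  # minutes

    def __post_init__(self) -> None:
        if self.min_distance < 1:
            raise ValueError("min_distance must be at least one sample")
        if self.min_prominence <= 0:
            raise ValueError("min_prominence must be positive")
        lo, hi = self.width_bounds
        if lo < 0 or hi < lo:
            raise ValueError("width_bounds must satisfy 0 <= min <= max")


@dataclass
class PressureEvent:
    """A detected load change.

    ``t_peak`` is the grid minute of the (plateau-middle) peak sample,
    ``width`` its duration proxy (width at half prominence, minutes)."""

    t_peak: int
    index: int
    direction: str  # "rising" | "falling"
    prominence: float
    width: float
    cluster_label: int | None = None


@dataclass
class EventWindow:
    """The -pre..+post minute trajectories around one event."""

    event: PressureEvent
    rel_time: np.ndarray
    pressure_traj: np.ndarray
    temp_traj: np.ndarray


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    centers: np.ndarray
    inertia_by_k: dict[int, float] = field(default_factory=dict)


@dataclass
class STAEntry:
    """Spike-triggered average of the relative temperature for one cluster,
    zero at the reference sample, plus its agreement with the cluster's
    pressure center."""

    rel_time: np.ndarray
    mean_delta_temp: np.ndarray
    n: int
    pearson_r: float | None = None
    spearman_rho: float | None = None


def smooth(values: np.ndarray, config: SmoothingConfig | None = None, interval: int = 1) -> np.ndarray:
    """Low-pass filter a gapless section; zero-phase by default.

    Sections shorter than the filter warm-up are returned unchanged with a
    warning.
    """
    config = config or SmoothingConfig()
    x = np.asarray(values, dtype=float)
    nyquist = 0.5 / interval
    if not config.cutoff < nyquist:
        raise ValueError("cutoff must lie below the Nyquist frequency of the series")
    b, a = signal.butter(config.order, config.cutoff / nyquist)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        warnings.warn("section shorter than filter warm-up; returning unfiltered copy")
        return x.copy()
    if config.zero_phase:
        return signal.filtfilt(b, a, x)
    return signal.lfilter(b, a, x)


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardise to zero mean and unit variance (population convention).

    A constant series has no defined variance; it maps to all zeros with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return x.copy()
    if x.max() == x.min():
        warnings.warn("constant series: z-score undefined, returning zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / x.std()


def _distance_filter(peaks: np.ndarray, prominences: np.ndarray, min_distance: int) -> np.ndarray:
    """Greedy suppression: keep the higher-prominence peak whenever two peaks
    are closer than ``min_distance`` samples (ties broken toward the earlier
    peak).  Returns a boolean keep-mask."""
    order = np.lexsort((peaks, -prominences))  # prominence desc, then index asc
    keep = np.ones(peaks.size, dtype=bool)
    taken: list[int] = []
    for i in order:
        if any(abs(int(peaks[i]) - p) < min_distance for p in taken):
            keep[i] = False
        else:
            taken.append(int(peaks[i]))
    return keep


def _detect_one_direction(
    x: np.ndarray, config: PeakConfig, direction: str, t: np.ndarray, interval: int
) -> list[PressureEvent]:
    y = x if direction == "rising" else -x
    peaks, _ = signal.find_peaks(y)  # plateau middle, lower-middle on ties
    if peaks.size == 0:
        return []
    prominences = signal.peak_prominences(y, peaks)[0]
    widths = signal.peak_widths(y, peaks, rel_height=0.5)[0] * interval
    keep = _distance_filter(peaks, prominences, max(1, config.min_distance // interval))
    keep &= prominences >= config.min_prominence
    lo, hi = config.width_bounds
    keep &= (widths >= lo) & (widths <= hi)
    return [
        PressureEvent(
            t_peak=int(t[i]),
            index=int(i),
            direction=direction,
            prominence=float(p),
            width=float(w),
        )
        for i, p, w in zip(peaks[keep], prominences[keep], widths[keep])
    ]


def detect_events(
    values: np.ndarray,
    config: PeakConfig | None = None,
    direction: str = "rising",
    t: np.ndarray | None = None,
    interval: int = 1,
) -> list[PressureEvent]:
    """Detect load events as filtered peaks of the (smoothed, standardised)
    total-load series.

    A peak is a sample whose two direct neighbours are smaller; equal-valued
    plateaus yield their middle sample (lower middle on even plateaus).
    Rising events are peaks of the series, falling events peaks of its
    negation.  Candidates are then filtered by minimal distance (higher
    prominence wins a conflict), minimal prominence and width-at-half-
    prominence bounds.  Series shorter than three samples yield no events.
    """
    config = config or PeakConfig()
    x = np.asarray(values, dtype=float)
    if t is None:
        t = np.arange(x.size, dtype=np.int64) * interval
    t = np.asarray(t)
    if x.size < 3:
        return []
    if direction == "both":
        events = _detect_one_direction(x, config, "rising", t, interval)
        events += _detect_one_direction(x, config, "falling", t, interval)
        return sorted(events, key=lambda e: (e.t_peak, e.direction))
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising', 'falling' or 'both'")
    return _detect_one_direction(x, config, direction, t, interval)


def upsample_sum_load(pressure: PressureSeries, interval_out: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Forward-fill the total-load series onto a finer grid (each frame is
    held for its native interval)."""
    if pressure.interval % interval_out != 0:
        raise ValueError("interval_out must divide the pressure interval")
    reps = pressure.interval // interval_out
    vals = np.repeat(pressure.sum_load, reps)
    t = (
        np.arange(vals.size, dtype=np.int64) * interval_out
        + (pressure.t[0] if pressure.n else 0)
    )
    return t, vals


def extract_windows(
    events: list[PressureEvent],
    t: np.ndarray,
    pressure: np.ndarray,
    temp: np.ndarray,
    pre: int = 5,
    post: int = 55,
) -> list[EventWindow]:
    """Cut the [-pre, +post] minute trajectories around each event.

    Both series must share the same 1-minute grid ``t``.  Windows that would
    cross the series boundary, or whose temperature trace contains a gap, are
    excluded.
    """
    t = np.asarray(t)
    pressure = np.asarray(pressure, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if not (t.size == pressure.size == temp.size):
        raise ValueError("t, pressure and temp must share one grid")
    rel = np.arange(-pre, post + 1, dtype=np.int64)
    windows: list[EventWindow] = []
    for ev in events:
        idx = np.flatnonzero(t == ev.t_peak)
        if idx.size == 0:
            continue
        i = int(idx[0])
        lo, hi = i - pre, i + post + 1
        if lo < 0 or hi > t.size:
            continue
        temp_traj = temp[lo:hi]
        if np.isnan(temp_traj).any() or np.isnan(pressure[lo:hi]).any():
            continue
        windows.append(
            EventWindow(
                event=ev,
                rel_time=rel.copy(),
                pressure_traj=pressure[lo:hi].copy(),
                temp_traj=temp_traj.copy(),
            )
        )
    return windows


def _scale_rows(X: np.ndarray) -> np.ndarray:
    """Per-window z-scoring ("input scaling"); constant rows map to zeros."""
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def select_elbow(inertia_by_k: dict[int, float]) -> int:
    """Pick K at the elbow of the inertia curve: the interior candidate with
    the maximum second difference (ties toward the smallest k).  With fewer
    than three candidates the largest candidate is returned."""
    ks = sorted(inertia_by_k)
    if not ks:
        raise ValueError("no cluster counts evaluated")
    if len(ks) < 3:
        return ks[-1]
    second = {
        ks[i]: inertia_by_k[ks[i - 1]] - 2 * inertia_by_k[ks[i]] + inertia_by_k[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    best = max(second.values())
    return min(k for k, v in second.items() if v == best)


def cluster_windows(
    windows: list[EventWindow],
    k_candidates=(2, 3, 4, 5, 6),
    seed: int = 0,
    mode: str = "trajectory",
    n_restarts: int = 10,
) -> ClusterResult:
    """Group event windows with k-means (Euclidean, multiple restarts).

    ``mode="trajectory"`` (default) clusters per-window rescaled pressure
    trajectories flattened to feature vectors; ``mode="width"`` clusters the
    scalar event-duration proxy instead.  K is selected by the elbow of the
    inertia curve over ``k_candidates``; candidates exceeding the number of
    windows are skipped with a warning.  Labels are deterministic for a
    fixed seed.
    """
    if not windows:
        raise ValueError("no windows to cluster")
    if mode == "trajectory":
        X = _scale_rows(np.vstack([w.pressure_traj for w in windows]))
    elif mode == "width":
        X = np.array([[w.event.width] for w in windows], dtype=float)
    else:
        raise ValueError("mode must be 'trajectory' or 'width'")

    fits: dict[int, KMeans] = {}
    inertia_by_k: dict[int, float] = {}
    for k in sorted(set(int(k) for k in k_candidates)):
        if k < 1:
            raise ValueError("cluster counts must be positive")
        if k > len(windows):
            warnings.warn(f"skipping k={k}: only {len(windows)} windows")
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        fits[k] = km
        inertia_by_k[k] = float(km.inertia_)

    k_sel = select_elbow(inertia_by_k)
    km = fits[k_sel]
    labels = km.labels_.astype(int)
    for w, lab in zip(windows, labels):
        w.event.cluster_label = int(lab)
    return ClusterResult(
        k=k_sel, labels=labels, centers=km.cluster_centers_.copy(), inertia_by_k=inertia_by_k
    )


#: Event-duration report bins, minutes; ">55" pools everything long.
DURATION_BINS = (20.0, 40.0, 57.5)
DURATION_LABELS = ("20", "40", ">55")


def duration_class(width: float) -> str:
    """Nearest duration bin (20 / 40 / >55 min) of an event-width proxy."""
    i = int(np.argmin([abs(width - b) for b in DURATION_BINS]))
    return DURATION_LABELS[i]


def spike_triggered_average(
    windows: list[EventWindow],
    pressure_center: np.ndarray | None = None,
    ref_rel_time: int = -1,
) -> STAEntry:
    """Pointwise mean of the relative temperature trajectories of one cluster.

    Each window's temperature is referenced to its sample at ``ref_rel_time``
    (one minute before the event), so the average is exactly zero there.
    When a pressure cluster center is supplied, Pearson r and Spearman rho
    between the center and the average are reported; they are absent when
    either trace is constant.
    """
    if not windows:
        raise ValueError("empty cluster")
    rel = windows[0].rel_time
    ref_idx = np.flatnonzero(rel == ref_rel_time)
    if ref_idx.size == 0:
        raise ValueError(f"reference rel_time {ref_rel_time} not inside the window")
    ref = int(ref_idx[0])
    deltas = np.vstack([w.temp_traj - w.temp_traj[ref] for w in windows])
    sta = deltas.mean(axis=0)
    sta[ref] = 0.0  # exact by construction; pin against rounding

    pearson_r = spearman_rho = None
    if pressure_center is not None:
        center = np.asarray(pressure_center, dtype=float)
        if center.size != sta.size:
            raise ValueError("pressure center and STA must share the time axis")
        if center.std() > 0 and sta.std() > 0:
            pearson_r = float(stats.pearsonr(center, sta)[0])
            spearman_rho = float(stats.spearmanr(center, sta)[0])
    return STAEntry(
        rel_time=rel.copy(),
        mean_delta_temp=sta,
        n=len(windows),
        pearson_r=pearson_r,
        spearman_rho=spearman_rho,
    )


def sta_by_cluster(windows: list[EventWindow], result: ClusterResult) -> dict[int, STAEntry]:
    """One spike-triggered average per cluster, scored against that cluster's
    pressure center (trajectory mode only)."""
    out: dict[int, STAEntry] = {}
    for label in range(result.k):
        members = [w for w, lab in zip(windows, result.labels) if lab == label]
        if not members:
            continue
        center = result.centers[label]
        center = center if center.size == members[0].rel_time.size else None
        out[label] = spike_triggered_average(members, pressure_center=center)
    return out
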