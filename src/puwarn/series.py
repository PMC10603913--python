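"""Core data containers for wearable sensor streams.

A subject's recording consists of a minute-gridded :class:`VitalSeries`
(SpO2, heart rate, skin temperature, each with a validity flag) and a
coarser-gridded :class:`PressureSeries` of force-grid frames.  Blank
readings are represented as ``NaN`` and are, by invariant, never flagged
valid.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, fields

import numpy as np

#: Vital channels carried by every :class:`VitalSeries`, in canonical order.
VITAL_CHANNELS = ("spo2", "hr", "temp")

#: Preexisting-condition flags carried by a :class:`SubjectProfile`.
CONDITION_FLAGS = ("diabetes", "immobile", "paraplegic", "prior_pu", "prior_pu_surgery")

GROUPS = ("patient", "control")


def _as_float(x, n: int | None = None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("channel arrays must be one-dimensional")
    if n is not None and a.size != n:
        raise ValueError(f"channel length {a.size} != grid length {n}")
    return a


def _as_bool(x, n: int) -> np.ndarray:
    a = np.asarray(x, dtype=bool)
    if a.shape != (n,):
        raise ValueError(f"flag length {a.shape} != grid length {n}")
    return a


@dataclass
class VitalSeries:
    """Equally spaced per-minute vital-sign records.

    Parameters
    ----------
    t:
        Minutes since subject start; strictly increasing, spaced by
        ``interval``.
    spo2, hr, temp:
        Channel values; ``NaN`` marks a blank reading.
    spo2_valid, hr_valid, temp_valid:
        Per-channel validity flags.  Default: valid wherever non-blank.
    spo2_filled, hr_filled, temp_filled:
        Set by :func:`puwarn.preprocess.forward_fill` on records whose value
        was carried forward; such records are valid but not original.
    """

    t: np.ndarray
    spo2: np.ndarray
    hr: np.ndarray
    temp: np.ndarray
    spo2_valid: np.ndarray | None = None
    hr_valid: np.ndarray | None = None
    temp_valid: np.ndarray | None = None
    spo2_filled: np.ndarray | None = None
    hr_filled: np.ndarray | None = None
    temp_filled: np.ndarray | None = None
    interval: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        n = self.t.size
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if n >= 2:
            steps = np.diff(self.t)
            if not np.all(steps == self.interval):
                raise ValueError("t must be strictly increasing with spacing == interval")
        for ch in VITAL_CHANNELS:
            vals = _as_float(getattr(self, ch), n)
            setattr(self, ch, vals)
            flag_name = f"{ch}_valid"
            flags = getattr(self, flag_name)
            if flags is None:
                flags = ~np.isnan(vals)
            flags = _as_bool(flags, n)
            if np.any(flags & np.isnan(vals)):
                raise ValueError(f"{ch}: a blank value must not be flagged valid")
            setattr(self, flag_name, flags)
            fill_name = f"{ch}_filled"
            filled = getattr(self, fill_name)
            filled = np.zeros(n, dtype=bool) if filled is None else _as_bool(filled, n)
            setattr(self, fill_name, filled)

    @property
    def n(self) -> int:
        return self.t.size

    def values(self, channel: str) -> np.ndarray:
        if channel not in VITAL_CHANNELS:
            raise KeyError(channel)
        return getattr(self, channel)

    def valid(self, channel: str) -> np.ndarray:
        if channel not in VITAL_CHANNELS:
            raise KeyError(channel)
        return getattr(self, f"{channel}_valid")

    def filled(self, channel: str) -> np.ndarray:
        if channel not in VITAL_CHANNELS:
            raise KeyError(channel)
        return getattr(self, f"{channel}_filled")

    def copy(self) -> "VitalSeries":
        return VitalSeries(
            t=self.t.copy(),
            spo2=self.spo2.copy(),
            hr=self.hr.copy(),
            temp=self.temp.copy(),
            spo2_valid=self.spo2_valid.copy(),
            hr_valid=self.hr_valid.copy(),
            temp_valid=self.temp_valid.copy(),
            spo2_filled=self.spo2_filled.copy(),
            hr_filled=self.hr_filled.copy(),
            temp_filled=self.temp_filled.copy(),
            interval=self.interval,
        )


@dataclass
class PressureSeries:
    """Per-frame pressure-grid readings (rows x cols, arbitrary units)."""

    t: np.ndarray
    grid: np.ndarray
    interval: int = 5

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must have shape (n_frames, rows, cols)")
        if self.grid.shape[0] != self.t.size:
            raise ValueError("number of frames must match number of timestamps")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.t.size >= 2 and not np.all(np.diff(self.t) == self.interval):
            raise ValueError("t must be strictly increasing with spacing == interval")
        if np.any(self.grid < 0):
            raise ValueError("pressure readings must be non-negative")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.grid.shape[1], self.grid.shape[2]

    @property
    def sum_load(self) -> np.ndarray:
        """Total load per frame: exact element sum of the grid."""
        return self.grid.sum(axis=(1, 2))

    def copy(self) -> "PressureSeries":
        return PressureSeries(t=self.t.copy(), grid=self.grid.copy(), interval=self.interval)


@dataclass
class Conditions:
    """Preexisting-condition flags of a subject."""

    diabetes: bool = False
    immobile: bool = False
    paraplegic: bool = False
    prior_pu: bool = False
    prior_pu_surgery: bool = False

    def any(self) -> bool:
        return any(getattr(self, f) for f in CONDITION_FLAGS)

    def true_flags(self) -> tuple[str, ...]:
        return tuple(f for f in CONDITION_FLAGS if getattr(self, f))

    def as_dict(self) -> dict[str, bool]:
        return {f: bool(getattr(self, f)) for f in CONDITION_FLAGS}


@dataclass
class SubjectProfile:
    """Subject metadata: group membership, physical data, conditions and
    finger-test diagnosis events (minute, "positive" | "negative")."""

    subject_id: str
    group: str
    age: float = 60.0
    height: float = 172.0
    weight: float = 80.0
    conditions: Conditions = field(default_factory=Conditions)
    diagnosis_events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.group == "control" and self.conditions.any():
            raise ValueError("control subjects must not carry condition flags")
        times = [t for t, _ in self.diagnosis_events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("diagnosis event times must be strictly increasing")
        results = [r for _, r in self.diagnosis_events]
        if any(r not in ("positive", "negative") for r in results):
            raise ValueError("finger-test result must be 'positive' or 'negative'")
        if results.count("positive") > 1:
            raise ValueError("at most one positive finger test per subject (study exit)")


@dataclass
class CohortDataset:
    """A bundle of per-subject streams plus generator provenance."""

    subjects: list[tuple[SubjectProfile, VitalSeries, PressureSeries]]
    config: object | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [p.subject_id for p, _, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def get(self, subject_id: str) -> tuple[SubjectProfile, VitalSeries, PressureSeries]:
        for entry in self.subjects:
            if entry[0].subject_id == subject_id:
                return entry
        raise KeyError(subject_id)

    def profiles(self) -> list[SubjectProfile]:
        return [p for p, _, _ in self.subjects]

    def copy(self) -> "CohortDataset":
        return CohortDataset(
            subjects=[(p, v.copy(), pr.copy()) for p, v, pr in self.subjects],
            config=_copy.deepcopy(self.config),
            seed=self.seed,
        )
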