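"""Insole pressure analysis: weight normalization and forefoot / midfoot /
rearfoot regional load summaries across shoe groups."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .series import PressureSeries

SHOE_GROUPS = ("orthopedic", "regular", "control")
REGIONS = ("forefoot", "midfoot", "rearfoot")

INSOLE_ROWS = 12
INSOLE_COLS = 4


@dataclass
class InsoleSeries:
    """A 4x12-element insole recording with subject weight and shoe group."""

    pressure: PressureSeries
    weight: float
    shoe_group: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        rows, cols = self.pressure.grid_shape
        if (rows, cols) != (INSOLE_ROWS, INSOLE_COLS):
            raise ValueError(f"insole grid must be {INSOLE_ROWS}x{INSOLE_COLS}, got {rows}x{cols}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.shoe_group not in SHOE_GROUPS:
            raise ValueError(f"unknown shoe group {self.shoe_group!r}")


@dataclass(frozen=True)
class RegionMap:
    """Contiguous assignment of the 12 insole rows (row 0 = toes) to
    forefoot / midfoot / rearfoot.  Default: rows 0-4 / 5-7 / 8-11."""

    forefoot: tuple[int, ...] = (0, 1, 2, 3, 4)
    midfoot: tuple[int, ...] = (5, 6, 7)
    rearfoot: tuple[int, ...] = (8, 9, 10, 11)

    def __post_init__(self) -> None:
        all_rows = sorted(self.forefoot + self.midfoot + self.rearfoot)
        if all_rows != list(range(INSOLE_ROWS)):
            raise ValueError("regions must partition the 12 rows exactly once")
        for name in REGIONS:
            rows = sorted(getattr(self, name))
            if rows and rows != list(range(rows[0], rows[-1] + 1)):
                raise ValueError(f"{name} rows must be contiguous")

    def rows(self, region: str) -> tuple[int, ...]:
        return getattr(self, region)


def normalize_by_weight(series: InsoleSeries) -> PressureSeries:
    """Divide every grid element by the subject's weight (a.u. per kg)."""
    if series.weight <= 0:
        raise ValueError("weight must be positive")
    return PressureSeries(
        t=series.pressure.t.copy(),
        grid=series.pressure.grid / series.weight,
        interval=series.pressure.interval,
    )


def region_loads(pressure: PressureSeries, region_map: RegionMap | None = None) -> dict[str, np.ndarray]:
    """Per-frame load sums per region; the three regions add up to the frame
    total exactly."""
    region_map = region_map or RegionMap()
    out = {}
    for region in REGIONS:
        rows = list(region_map.rows(region))
        out[region] = pressure.grid[:, rows, :].sum(axis=(1, 2))
    return out


def group_summary(
    insoles: list[InsoleSeries], region_map: RegionMap | None = None
) -> dict[str, dict[str, dict[str, float]]]:
    """Mean and peak weight-normalized load per shoe group and region.

    The mean pools all frames of all subjects in the group; the peak is each
    subject's maximum frame load, averaged across the group.  A "total"
    pseudo-region summarises the whole sole.  Groups without subjects are
    omitted with a warning.
    """
    region_map = region_map or RegionMap()
    per_group: dict[str, dict[str, list]] = {
        g: {r: [] for r in REGIONS + ("total",)} for g in SHOE_GROUPS
    }
    peaks: dict[str, dict[str, list]] = {
        g: {r: [] for r in REGIONS + ("total",)} for g in SHOE_GROUPS
    }
    for ins in insoles:
        norm = normalize_by_weight(ins)
        loads = region_loads(norm, region_map)
        loads["total"] = norm.sum_load
        for region, vals in loads.items():
            if vals.size == 0:
                continue
            per_group[ins.shoe_group][region].append(vals)
            peaks[ins.shoe_group][region].append(float(vals.max()))

    summary: dict[str, dict[str, dict[str, float]]] = {}
    for group in SHOE_GROUPS:
        if not any(per_group[group][r] for r in per_group[group]):
            warnings.warn(f"no subjects in shoe group {group!r}; omitted")
            continue
        summary[group] = {}
        for region in REGIONS + ("total",):
            frames = per_group[group][region]
            if not frames:
                continue
            pooled = np.concatenate(frames)
            summary[group][region] = {
                "mean_load": float(pooled.mean()),
                "peak_load": float(np.mean(peaks[group][region])),
            }
    return summary


@dataclass(frozen=True)
class InsoleGeneratorConfig:
    """Synthetic insole streams: a weight-proportional footprint (heel-heavy,
    light midfoot) plus random gait spikes whose amplitude the orthopedic
    shoe attenuates."""

    duration: int = 600
    interval: int = 1
    load_per_kg: float = 0.05  # baseline a.u. per kg per element-row unit
    row_profile: tuple[float, ...] = (
        1.0, 1.1, 1.2, 1.1, 1.0,   # forefoot
        0.3, 0.3, 0.3,             # midfoot
        1.3, 1.5, 1.5, 1.4,        # rearfoot
    )
    spike_rate: float = 0.05      # spikes per minute
    spike_amplitude: float = 3.0  # multiple of the local baseline
    noise_sd: float = 0.02
    attenuation: dict[str, float] = field(
        default_factory=lambda: {"orthopedic": 0.5, "regular": 1.0, "control": 1.0}
    )


def generate_insole(
    subject_id: str,
    weight: float,
    shoe_group: str,
    config: InsoleGeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> InsoleSeries:
    """Generate one synthetic insole recording; deterministic from seed."""
    config = config or InsoleGeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = config.duration // config.interval
    profile = np.asarray(config.row_profile, dtype=float)
    if profile.size != INSOLE_ROWS:
        raise ValueError("row_profile must cover the 12 rows")
    base = weight * config.load_per_kg * profile[None, :, None]
    grid = base * np.ones((n, INSOLE_ROWS, INSOLE_COLS))
    grid += rng.normal(0.0, config.noise_sd * weight * config.load_per_kg, grid.shape)
    atten = config.attenuation.get(shoe_group, 1.0)
    spikes = rng.random(n) < config.spike_rate * config.interval
    grid[spikes] *= 1.0 + config.spike_amplitude * atten
    np.clip(grid, 0.0, None, out=grid)
    pressure = PressureSeries(
        t=np.arange(n, dtype=np.int64) * config.interval, grid=grid, interval=config.interval
    )
    return InsoleSeries(pressure=pressure, weight=weight, shoe_group=shoe_group, subject_id=subject_id)


def generate_insole_cohort(
    n_orthopedic: int,
    n_regular: int,
    n_control: int,
    config: InsoleGeneratorConfig | None = None,
    seed: int | None = None,
) -> list[InsoleSeries]:
    """A cohort of synthetic insole recordings with per-subject spawned
    seeds and N(80, 15) kg weights."""
    config = config or InsoleGeneratorConfig()
    master = np.random.SeedSequence(seed)
    sizes = {"orthopedic": n_orthopedic, "regular": n_regular, "control": n_control}
    n_total = sum(sizes.values())
    children = master.spawn(n_total + 1)
    weight_rng = np.random.default_rng(children[0])
    out: list[InsoleSeries] = []
    k = 0
    for group, count in sizes.items():
        for i in range(count):
            weight = float(np.clip(weight_rng.normal(80.0, 15.0), 40.0, 180.0))
            rng = np.random.default_rng(children[k + 1])
            out.append(
                generate_insole(f"{group[:3].upper()}{i + 1:03d}", weight, group, config, rng=rng)
            )
            k += 1
    return out
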