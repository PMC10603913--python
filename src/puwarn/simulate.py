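"""Synthetic cohort generator for wearable sensor streams.

The generator emulates the statistical structure the downstream analysis
assumes: mean-reverting vital-sign noise around group-specific levels,
pressure-load events of scheduled duration coupled into the skin-temperature
channel, burst-like invalid readings, missing-timestamp gaps and an optional
step-wise SpO2 decline episode ahead of a diagnosis.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .series import (
    CONDITION_FLAGS,
    CohortDataset,
    Conditions,
    PressureSeries,
    SubjectProfile,
    VitalSeries,
)

# Default group vital-sign levels (mean, sd): tissue SpO2 in %, heart rate in
# bpm, skin temperature in deg C.  Patients: 91.3 +/- 2.9 % SpO2,
# 70.2 +/- 10.8 bpm, 36.0 +/- 0.7 C; controls: 98.5 +/- 0.9 %,
# 57.4 +/- 7.0 bpm, 35.3 +/- 0.4 C.


@dataclass(frozen=True)
class GroupParams:
    """Marginal (mean, sd) per vital channel for one subject group."""

    spo2_mean: float = 95.0
    spo2_sd: float = 2.0
    hr_mean: float = 65.0
    hr_sd: float = 9.0
    temp_mean: float = 35.6
    temp_sd: float = 0.5

    def mean(self, channel: str) -> float:
        return getattr(self, f"{channel}_mean")

    def sd(self, channel: str) -> float:
        return getattr(self, f"{channel}_sd")


PATIENT_VITALS = GroupParams(91.3, 2.9, 70.2, 10.8, 36.0, 0.7)
CONTROL_VITALS = GroupParams(98.5, 0.9, 57.4, 7.0, 35.3, 0.4)

#: Physical clipping ranges applied to generated channels.
CLIP_RANGES = {"spo2": (0.0, 100.0), "hr": (0.0, 300.0), "temp": (20.0, 45.0)}


@dataclass(frozen=True)
class PressureEventSpec:
    """A scheduled load event: onset minute, duration in minutes, per-element
    amplitude in a.u. added on the event sub-block."""

    start: int
    duration: int
    amplitude: float = 5.0


@dataclass
class GeneratorConfig:
    """All knobs of the per-subject stream generator.

    ``vitals_interval`` and ``pressure_interval`` must divide ``duration``;
    fractions live in [0, 1]; standard deviations are non-negative.
    """

    duration: int = 1440
    vitals_interval: int = 1
    pressure_interval: int = 5
    grid_shape: tuple[int, int] = (5, 5)
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: {"patient": PATIENT_VITALS, "control": CONTROL_VITALS}
    )
    #: Mean-reversion time constant of the AR(1) vital-sign noise, minutes.
    ar_tau: float = 30.0
    #: Stationary fraction of invalid (blank) readings, per channel or scalar.
    invalid_fraction: float | dict[str, float] = 0.0
    #: Mean length of an invalid burst, minutes (two-state Markov model).
    invalid_burst_length: float = 5.0
    #: Probability per minute of opening a missing-timestamp gap.
    gap_rate: float = 0.0
    #: Mean gap length, minutes.
    gap_mean_length: float = 5.0
    #: Scheduled pressure-load events.
    pressure_events: tuple[PressureEventSpec, ...] = ()
    #: Per-element baseline load and its frame-to-frame noise sd, a.u.
    baseline_load: float = 1.0
    pressure_noise_sd: float = 0.05
    #: Event footprint on the grid (contiguous sub-block, centered).
    event_block: tuple[int, int] = (3, 3)
    #: Skin-temperature coupling: deg C per unit of z-scored total load, and
    #: first-order lag in minutes (rising load -> delayed temperature rise).
    temp_coupling_gain: float = 0.5
    temp_coupling_lag: float = 5.0
    #: Additive per-channel mean shifts applied when a condition flag is set,
    #: e.g. {"prior_pu_surgery": {"spo2": -2.2}}.
    condition_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int | None = None

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("vitals_interval", "pressure_interval"):
            iv = getattr(self, name)
            if iv <= 0:
                raise ValueError(f"{name} must be positive")
            if self.duration % iv != 0:
                raise ValueError(f"{name} must divide duration")
        for frac in self._fractions():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("invalid_fraction must lie in [0, 1]")
        for params in self.group_params.values():
            for ch in ("spo2", "hr", "temp"):
                if params.sd(ch) < 0:
                    raise ValueError("channel sd must be non-negative")
        if self.pressure_noise_sd < 0:
            raise ValueError("pressure_noise_sd must be non-negative")
        br, bc = self.event_block
        gr, gc = self.grid_shape
        if not (1 <= br <= gr and 1 <= bc <= gc):
            raise ValueError("event_block must fit inside grid_shape")

    def _fractions(self):
        if isinstance(self.invalid_fraction, dict):
            return list(self.invalid_fraction.values())
        return [self.invalid_fraction]

    def channel_invalid_fraction(self, channel: str) -> float:
        if isinstance(self.invalid_fraction, dict):
            return float(self.invalid_fraction.get(channel, 0.0))
        return float(self.invalid_fraction)


def _ar1(rng: np.random.Generator, n: int, mean: float, sd: float, tau: float, dt: float) -> np.ndarray:
    """Stationary first-order autoregressive (mean-reverting) noise."""
    if n == 0:
        return np.empty(0)
    if sd == 0.0:
        return np.full(n, mean)
    phi = math.exp(-dt / tau) if tau > 0 else 0.0
    eps = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return mean + signal.lfilter([1.0], [1.0, -phi], eps)


def _markov_mask(rng: np.random.Generator, n: int, frac: float, mean_len: float) -> np.ndarray:
    """Two-state Markov indicator with stationary fraction ``frac`` of True
    samples organised in bursts of mean length ``mean_len``."""
    if n == 0 or frac <= 0.0:
        return np.zeros(n, dtype=bool)
    if frac >= 1.0:
        return np.ones(n, dtype=bool)
    p_exit = min(1.0, 1.0 / max(mean_len, 1.0))
    p_enter = min(1.0, frac * p_exit / (1.0 - frac))
    u = rng.random(n + 1)
    out = np.empty(n, dtype=bool)
    state = u[n] < frac
    for i in range(n):
        out[i] = state
        if state:
            state = u[i] >= p_exit
        else:
            state = u[i] < p_enter
    return out


def _lagged(x: np.ndarray, lag: float, dt: float) -> np.ndarray:
    """First-order low-pass response of x with time constant ``lag``."""
    if lag <= 0:
        return x.copy()
    alpha = 1.0 - math.exp(-dt / lag)
    return signal.lfilter([alpha], [1.0, alpha - 1.0], x)


def _blank(series_vals: np.ndarray, flags: np.ndarray, mask: np.ndarray) -> None:
    series_vals[mask] = np.nan
    flags[mask] = False


def generate_subject(
    profile: SubjectProfile,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[VitalSeries, PressureSeries]:
    """Generate one subject's vital and pressure streams.

    Vitals are AR(1) mean-reverting noise around the group means (shifted by
    any configured condition offsets), clipped to physical ranges.  Skin
    temperature additionally tracks the z-scored total pressure load through
    a first-order lag with the configured gain.  Scheduled pressure events
    add their amplitude on a centered contiguous sub-block of the grid.
    Validity and gap corruption is applied last.

    Fully deterministic given ``(profile, config, seed)``; an explicit
    ``rng`` overrides ``config.seed``.
    """
    config.validate()
    if profile.group not in config.group_params:
        raise ValueError(f"no generator parameter set for group {profile.group!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = config.group_params[profile.group]

    # --- pressure frames first (temperature couples to them) -------------
    n_p = config.duration // config.pressure_interval
    t_p = np.arange(n_p, dtype=np.int64) * config.pressure_interval
    rows, cols = config.grid_shape
    grid = rng.normal(config.baseline_load, config.pressure_noise_sd, (n_p, rows, cols))
    np.clip(grid, 0.0, None, out=grid)
    br, bc = config.event_block
    r0, c0 = (rows - br) // 2, (cols - bc) // 2
    for ev in config.pressure_events:
        on = (t_p >= ev.start) & (t_p < ev.start + ev.duration)
        grid[on, r0 : r0 + br, c0 : c0 + bc] += ev.amplitude
    pressure = PressureSeries(t=t_p, grid=grid, interval=config.pressure_interval)

    # --- vitals ------------------------------------------------------------
    n_v = config.duration // config.vitals_interval
    t_v = np.arange(n_v, dtype=np.int64) * config.vitals_interval
    offsets = {ch: 0.0 for ch in ("spo2", "hr", "temp")}
    for flag in profile.conditions.true_flags():
        for ch, shift in config.condition_offsets.get(flag, {}).items():
            offsets[ch] += shift

    dt = float(config.vitals_interval)
    channels: dict[str, np.ndarray] = {}
    for ch in ("spo2", "hr", "temp"):
        channels[ch] = _ar1(rng, n_v, params.mean(ch) + offsets[ch], params.sd(ch), config.ar_tau, dt)

    load = pressure.sum_load
    if n_p > 0 and load.std() > 0:
        z = (load - load.mean()) / load.std()
        reps = config.pressure_interval // config.vitals_interval
        z_up = np.repeat(z, reps)[:n_v]
        channels["temp"] = channels["temp"] + config.temp_coupling_gain * _lagged(
            z_up, config.temp_coupling_lag, dt
        )
    for ch, (lo, hi) in CLIP_RANGES.items():
        np.clip(channels[ch], lo, hi, out=channels[ch])

    flags = {}
    for ch in ("spo2", "hr", "temp"):
        mask = _markov_mask(
            rng, n_v, config.channel_invalid_fraction(ch), config.invalid_burst_length
        )
        f = np.ones(n_v, dtype=bool)
        _blank(channels[ch], f, mask)
        flags[ch] = f

    if config.gap_rate > 0:
        gap_frac = min(
            1.0, config.gap_rate * config.gap_mean_length / (1.0 + config.gap_rate * config.gap_mean_length)
        )
        gaps = _markov_mask(rng, n_v, gap_frac, config.gap_mean_length)
        for ch in ("spo2", "hr", "temp"):
            _blank(channels[ch], flags[ch], gaps)

    vitals = VitalSeries(
        t=t_v,
        spo2=channels["spo2"],
        hr=channels["hr"],
        temp=channels["temp"],
        spo2_valid=flags["spo2"],
        hr_valid=flags["hr"],
        temp_valid=flags["temp"],
        interval=config.vitals_interval,
    )
    return vitals, pressure


def inject_pu_episode(
    vitals: VitalSeries,
    onset: int,
    drop: float,
    decline_duration: int,
    hold_duration: int = 0,
) -> VitalSeries:
    """Superimpose a linear SpO2 decline episode on a copy of ``vitals``.

    The SpO2 level falls linearly by ``drop`` percentage points over
    ``decline_duration`` minutes starting at ``onset`` and stays at the
    lowered level through ``hold_duration`` minutes (inclusive end); other
    channels and the noise/validity structure are untouched.
    """
    if drop < 0:
        raise ValueError("drop must be non-negative")
    if decline_duration <= 0:
        raise ValueError("decline_duration must be positive")
    if hold_duration < 0:
        raise ValueError("hold_duration must be non-negative")
    if vitals.n == 0:
        raise ValueError("cannot inject an episode into an empty series")
    if onset < vitals.t[0] or onset + decline_duration + hold_duration > vitals.t[-1]:
        raise ValueError("episode exceeds series bounds")

    out = vitals.copy()
    rel = (out.t - onset).astype(float)
    delta = np.zeros(out.n)
    declining = (rel >= 0) & (rel < decline_duration)
    delta[declining] = -drop * rel[declining] / decline_duration
    holding = (rel >= decline_duration) & (rel <= decline_duration + hold_duration)
    delta[holding] = -drop
    present = ~np.isnan(out.spo2)
    out.spo2[present] = np.clip(out.spo2[present] + delta[present], 0.0, 100.0)
    return out


#: Condition-flag prevalences used when sampling patient profiles.  Diabetes
#: ~25% and immobility ~50% of the study group; the remaining flags are
#: plausible fill-ins.  ``prior_pu_surgery`` is sampled conditional on
#: ``prior_pu``.
DEFAULT_PREVALENCES = {
    "diabetes": 0.25,
    "immobile": 0.50,
    "paraplegic": 0.10,
    "prior_pu": 0.35,
    "prior_pu_surgery_given_prior_pu": 0.60,
}


def _sample_profile(
    rng: np.random.Generator, subject_id: str, group: str, prevalences: dict[str, float]
) -> SubjectProfile:
    if group == "patient":
        age = float(np.clip(rng.normal(70.0, 10.0), 18.0, 100.0))
        conditions = Conditions(
            diabetes=bool(rng.random() < prevalences["diabetes"]),
            immobile=bool(rng.random() < prevalences["immobile"]),
            paraplegic=bool(rng.random() < prevalences["paraplegic"]),
        )
        prior = rng.random() < prevalences["prior_pu"]
        conditions.prior_pu = bool(prior)
        conditions.prior_pu_surgery = bool(
            prior and rng.random() < prevalences["prior_pu_surgery_given_prior_pu"]
        )
    else:
        age = float(np.clip(rng.normal(35.0, 10.0), 18.0, 100.0))
        conditions = Conditions()
    height = float(np.clip(rng.normal(172.0, 9.0), 140.0, 210.0))
    weight = float(np.clip(rng.normal(80.0, 15.0), 40.0, 180.0))
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        age=age,
        height=height,
        weight=weight,
        conditions=conditions,
    )


def generate_cohort(
    n_patients: int,
    n_controls: int,
    config: GeneratorConfig,
    seed: int | None = None,
    prevalences: dict[str, float] | None = None,
) -> CohortDataset:
    """Generate a cohort of independent subjects.

    Per-subject random streams are spawned deterministically from the master
    seed, so a cohort is reproducible as a whole and any prefix of it is
    stable under changes of the remaining subjects.
    """
    if n_patients < 0 or n_controls < 0:
        raise ValueError("cohort counts must be non-negative")
    config.validate()
    if seed is None:
        seed = config.seed
    prev = dict(DEFAULT_PREVALENCES)
    if prevalences:
        prev.update(prevalences)

    master = np.random.SeedSequence(seed)
    n_total = n_patients + n_controls
    children = master.spawn(n_total + 1)
    profile_rng = np.random.default_rng(children[0])

    subjects = []
    labels = [("patient", f"P{i + 1:03d}") for i in range(n_patients)]
    labels += [("control", f"C{i + 1:03d}") for i in range(n_controls)]
    for k, (group, sid) in enumerate(labels):
        profile = _sample_profile(profile_rng, sid, group, prev)
        rng = np.random.default_rng(children[k + 1])
        vitals, pressure = generate_subject(profile, config, rng=rng)
        subjects.append((profile, vitals, pressure))
    return CohortDataset(subjects=subjects, config=dataclasses.replace(config), seed=seed)
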