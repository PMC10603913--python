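"""Group-level cohort statistics: per-subject mean vitals, patient-vs-control
comparisons and condition stratification with Welch's unequal-variances
t-test (two-sided, significance flagged at alpha = 0.001).

Comparisons run across subject-level means, not pooled minutes, to avoid
pseudo-replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import CONDITION_FLAGS, VITAL_CHANNELS, CohortDataset

ALPHA = 0.001

#: Channels compared at the group level; "pressure" is the mean total load.
COMPARISON_CHANNELS = VITAL_CHANNELS + ("pressure",)


@dataclass
class SubjectSummary:
    subject_id: str
    group: str
    means: dict[str, float]
    sds: dict[str, float]
    mean_pressure_load: float


@dataclass
class GroupComparison:
    channel: str
    stratifier: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    welch_t: float
    welch_df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def subject_means(dataset: CohortDataset) -> list[SubjectSummary]:
    """Per-subject arithmetic mean and sd over valid samples, per channel,
    plus the mean total pressure load.  Subjects without any valid vital
    sample are excluded with a warning."""
    out: list[SubjectSummary] = []
    for profile, vitals, pressure in dataset:
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        for ch in VITAL_CHANNELS:
            mask = vitals.valid(ch) & ~np.isnan(vitals.values(ch))
            if mask.any():
                vals = vitals.values(ch)[mask]
                means[ch] = float(vals.mean())
                sds[ch] = float(vals.std())
        if not means:
            warnings.warn(f"subject {profile.subject_id}: no valid data, excluded")
            continue
        load = pressure.sum_load
        out.append(
            SubjectSummary(
                subject_id=profile.subject_id,
                group=profile.group,
                means=means,
                sds=sds,
                mean_pressure_load=float(load.mean()) if load.size else float("nan"),
            )
        )
    return out


def welch_test(
    group_a, group_b, channel: str = "", stratifier: str = ""
) -> GroupComparison:
    """Welch's unequal-variances t-test between two lists of subject means.

    Two-sided p with Welch-Satterthwaite degrees of freedom; identical
    groups give t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two subjects")
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        t_stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return GroupComparison(
        channel=channel,
        stratifier=stratifier,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        welch_t=float(t_stat),
        welch_df=float(df),
        p_value=float(p),
    )


def _channel_values(summaries: list[SubjectSummary], channel: str) -> list[float]:
    if channel == "pressure":
        return [s.mean_pressure_load for s in summaries]
    return [s.means[channel] for s in summaries if channel in s.means]


def compare_groups(dataset: CohortDataset) -> dict[str, GroupComparison]:
    """Patient-vs-control comparison per channel across subject means."""
    summaries = subject_means(dataset)
    patients = [s for s in summaries if s.group == "patient"]
    controls = [s for s in summaries if s.group == "control"]
    out: dict[str, GroupComparison] = {}
    for ch in COMPARISON_CHANNELS:
        a, b = _channel_values(patients, ch), _channel_values(controls, ch)
        if len(a) >= 2 and len(b) >= 2:
            out[ch] = welch_test(a, b, channel=ch, stratifier="group")
    return out


def stratify_by_condition(dataset: CohortDataset, flag: str) -> dict[str, GroupComparison]:
    """Split patients on a condition flag and compare every channel
    (including mean pressure load) between the strata.

    Group A carries the flag, group B does not; an empty stratum is an
    input error.
    """
    if flag not in CONDITION_FLAGS:
        raise ValueError(f"unknown condition flag {flag!r}")
    patient_set = CohortDataset(
        subjects=[s for s in dataset.subjects if s[0].group == "patient"],
        config=dataset.config,
        seed=dataset.seed,
    )
    with_flag = {p.subject_id for p in patient_set.profiles() if getattr(p.conditions, flag)}
    summaries = subject_means(patient_set)
    group_a = [s for s in summaries if s.subject_id in with_flag]
    group_b = [s for s in summaries if s.subject_id not in with_flag]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(f"stratum too small for flag {flag!r} (need >= 2 subjects each)")
    out: dict[str, GroupComparison] = {}
    for ch in COMPARISON_CHANNELS:
        a, b = _channel_values(group_a, ch), _channel_values(group_b, ch)
        if len(a) >= 2 and len(b) >= 2:
            out[ch] = welch_test(a, b, channel=ch, stratifier=flag)
    return out
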