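"""End-to-end orchestration: simulate -> preprocess -> events -> predict ->
cohort (-> foot), writing the documented CSV artifacts per stage."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import cohort as cohort_mod
from . import events as events_mod
from . import foot as foot_mod
from . import io
from . import predictor as predictor_mod
from . import preprocess as pre
from .series import CohortDataset
from .simulate import GeneratorConfig, generate_cohort

log = logging.getLogger("puwarn")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str, counts: dict, fn):
    start = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise PipelineError(name, exc) from exc
    log.info("stage %s done in %.2fs", name, time.perf_counter() - start)
    return result


def stage_simulate(config: io.RunConfig, out_dir: Path) -> CohortDataset:
    gen = GeneratorConfig(duration=config.duration, **config.generator)
    dataset = generate_cohort(config.n_patients, config.n_controls, gen, seed=config.seed)
    raw = io.ensure_dir(out_dir / "raw")
    io.write_subjects(dataset.profiles(), raw / "subjects.csv")
    for profile, vitals, pressure in dataset:
        io.write_vitals(vitals, raw / f"vitals_{profile.subject_id}.csv")
        io.write_pressure(pressure, raw / f"pressure_{profile.subject_id}.csv")
    return dataset


def stage_preprocess(config: io.RunConfig, dataset: CohortDataset, out_dir: Path) -> CohortDataset:
    processed = []
    sections_all = []
    pdir = io.ensure_dir(out_dir / "preprocessed")
    for profile, vitals, pressure in dataset:
        clean = pre.preprocess_series(vitals, config.bounds, config.quality)
        sections = pre.segment_sections(clean, config.quality, subject_id=profile.subject_id)
        sections_all.extend(sections)
        io.write_vitals(clean, pdir / f"vitals_{profile.subject_id}.csv")
        io.write_sections(sections, pdir / f"sections_{profile.subject_id}.csv")
        processed.append((profile, clean, pressure))
    io.write_sections(sections_all, pdir / "sections.csv")
    return CohortDataset(subjects=processed, config=dataset.config, seed=dataset.seed)


def stage_events(config: io.RunConfig, dataset: CohortDataset, out_dir: Path) -> dict:
    edir = io.ensure_dir(out_dir / "events")
    windows = []
    for profile, vitals, pressure in dataset:
        if pressure.n < 3:
            continue
        t_up, load = events_mod.upsample_sum_load(pressure, vitals.interval)
        smoothed = events_mod.smooth(load, config.smoothing, interval=vitals.interval)
        z = events_mod.zscore(smoothed)
        evs = events_mod.detect_events(
            z, config.peaks, direction=config.event_direction, t=t_up, interval=vitals.interval
        )
        temp = np.where(vitals.temp_valid, vitals.temp, np.nan)
        n = min(t_up.size, vitals.n)
        wins = events_mod.extract_windows(evs, t_up[:n], z[:n], temp[:n])
        io.write_events(evs, edir / f"events_{profile.subject_id}.csv")
        windows.extend(wins)

    result = None
    if len(windows) >= 2:
        ks = [k for k in config.k_candidates if k <= len(windows)]
        if ks:
            result = events_mod.cluster_windows(windows, ks, seed=config.seed)
            for label, entry in events_mod.sta_by_cluster(windows, result).items():
                io.write_sta(entry, edir / f"sta_cluster{label}.csv")
    return {"windows": windows, "clusters": result}


def stage_predict(config: io.RunConfig, dataset: CohortDataset, out_dir: Path):
    pdir = io.ensure_dir(out_dir / "predictor")
    summaries = []
    for profile, vitals, _pressure in dataset:
        trace = predictor_mod.diff_and_state(vitals, config.predictor)
        io.write_predictor_trace(trace, pdir / f"predictor_{profile.subject_id}.csv")
        summaries.append(
            predictor_mod.alarm_events(trace, config.predictor, subject_id=profile.subject_id)
        )
    io.write_alarms(summaries, pdir / "alarms.csv")
    return summaries


def stage_cohort(config: io.RunConfig, dataset: CohortDataset, out_dir: Path):
    cdir = io.ensure_dir(out_dir / "cohort")
    summaries = cohort_mod.subject_means(dataset)
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            **{f"mean_{ch}": s.means.get(ch) for ch in ("spo2", "hr", "temp")},
            "mean_pressure_load": s.mean_pressure_load,
        }
        for s in summaries
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(cdir / "cohort_summary.csv", index=False)
    comparisons = list(cohort_mod.compare_groups(dataset).values())
    if config.stratify:
        try:
            comparisons += list(cohort_mod.stratify_by_condition(dataset, config.stratify).values())
        except ValueError as exc:
            log.warning("stratification skipped: %s", exc)
    io.write_comparisons(comparisons, cdir / "comparisons.csv")
    return comparisons


def stage_foot(config: io.RunConfig, out_dir: Path):
    fdir = io.ensure_dir(out_dir / "foot")
    insoles = foot_mod.generate_insole_cohort(
        config.foot.n_orthopedic,
        config.foot.n_regular,
        config.foot.n_control,
        foot_mod.InsoleGeneratorConfig(duration=config.foot.duration),
        seed=config.seed,
    )
    summary = foot_mod.group_summary(insoles)
    io.write_foot_summary(summary, fdir / "foot_summary.csv")
    return summary


def run_pipeline(config: io.RunConfig) -> int:
    """Execute all configured stages; returns 0 on success.

    Artifacts are stamped with the configuration hash and seed via
    ``run_manifest.json``; a stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out_dir = io.ensure_dir(config.out_dir)
    dataset = _stage("simulate", {}, lambda: stage_simulate(config, out_dir))
    dataset = _stage("preprocess", {}, lambda: stage_preprocess(config, dataset, out_dir))
    event_info = _stage("events", {}, lambda: stage_events(config, dataset, out_dir))
    alarms = _stage("predict", {}, lambda: stage_predict(config, dataset, out_dir))
    comparisons = _stage("cohort", {}, lambda: stage_cohort(config, dataset, out_dir))
    foot_summary = None
    if config.foot.enabled:
        foot_summary = _stage("foot", {}, lambda: stage_foot(config, out_dir))

    manifest = {
        "config_hash": io.config_hash(config),
        "seed": config.seed,
        "n_subjects": len(dataset),
        "n_event_windows": len(event_info["windows"]),
        "selected_k": event_info["clusters"].k if event_info["clusters"] else None,
        "n_alarm_summaries": len(alarms),
        "n_comparisons": len(comparisons),
        "foot_groups": sorted(foot_summary) if foot_summary else [],
    }
    with open(Path(config.out_dir) / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return 0
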