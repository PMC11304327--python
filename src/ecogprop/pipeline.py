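"""End-to-end pipeline: simulate → detect → score → cluster → report.

Thin orchestration over the library modules, shared by the numbered
analysis drivers and by the determinism checks.  Every stage is a pure
function of (config, seed), so two runs with the same seed produce
byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import fit_clusters
from .cohort import summarize_cohort, weekly_track, weekly_track_table
from .detection import detect_and_classify
from .io import EcogRecording, RunConfig, write_tables
from .metrics import compute_event_metrics, session_power_stats
from .propagation import correlation_profile, saturation_filter
from .synthetic import CohortConfig, synth_session


def simulate_cohort(
    config: CohortConfig,
    groups: dict[str, list[str]],
    weeks: int,
    seed: int,
    session_s: float,
) -> tuple[list[EcogRecording], pd.DataFrame]:
    """Simulate sessions for each animal × week; returns recordings + truth.

    ``groups`` maps group name → list of animal ids.  Seeds are derived
    deterministically per (group, animal, week).
    """
    ss = np.random.SeedSequence(seed)
    recordings: list[EcogRecording] = []
    truth_rows = []
    idx = 0
    for group in sorted(groups):
        for animal in groups[group]:
            for week in range(weeks):
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
                # spawn() advances the sequence, keeping per-session seeds
                # reproducible as a function of iteration order
                rec, specs = synth_session(
                    config, group, week, child, animal_id=animal, session_s=session_s
                )
                recordings.append(rec)
                for sp in specs:
                    truth_rows.append(
                        {
                            "session_idx": idx,
                            "animal_id": animal,
                            "group": group,
                            "week": week,
                            "type": sp.type,
                            "onset_s": sp.onset,
                            "duration_s": sp.duration,
                            "regime": sp.regime,
                            "amplitude": sp.amplitude,
                        }
                    )
                idx += 1
    return recordings, pd.DataFrame(truth_rows)


def score_sessions(
    recordings: list[EcogRecording], run_config: RunConfig
) -> pd.DataFrame:
    """Detect, classify and propagation-score every session.

    Returns one event table for the whole cohort with correlation
    profiles, saturation flags and (for retained events) power metrics.
    """
    rows = []
    eid = 0
    for rec in recordings:
        events = detect_and_classify(rec, run_config)
        pairs = [
            (ev, correlation_profile(ev, rec.rail, run_config.rail_tolerance))
            for ev in events
        ]
        saturation_filter(pairs, rec.rail, run_config.saturation_exclusion_fraction)
        stats = session_power_stats(rec, run_config) if events else None
        for ev, prof in pairs:
            row = {
                "event_id": eid,
                "animal_id": rec.animal_id,
                "group": rec.group,
                "week": rec.week,
                "type": ev.type,
                "start": ev.start,
                "end": ev.end,
                "duration_s": ev.duration_s,
                "r_1mm": prof.r_1mm,
                "r_2mm": prof.r_2mm,
                "sat_frac_focus": prof.sat_frac_focus,
                "sat_frac_d1": prof.sat_frac_d1,
                "sat_frac_d2": prof.sat_frac_d2,
                "metrics_excluded": prof.metrics_excluded,
            }
            if not prof.metrics_excluded:
                m = compute_event_metrics(ev, stats, run_config)
                row.update(
                    {
                        "max_band_power": m.max_band_power,
                        "auc": m.auc,
                        "norm_max_power_d1": m.norm_max_power["d1mm"],
                        "norm_max_power_d2": m.norm_max_power["d2mm"],
                        "norm_auc_d1": m.norm_auc["d1mm"],
                        "norm_auc_d2": m.norm_auc["d2mm"],
                        "norm_duration_d1": m.norm_duration["d1mm"],
                        "norm_duration_d2": m.norm_duration["d2mm"],
                        "arrival_focus_s": m.arrival["focus"],
                        "arrival_d1_s": m.arrival["d1mm"],
                        "arrival_d2_s": m.arrival["d2mm"],
                        "delay_d1_s": m.delay_d1,
                        "delay_d2_s": m.delay_d2,
                    }
                )
            rows.append(row)
            eid += 1
    return pd.DataFrame(rows)


def cluster_event_table(
    events: pd.DataFrame, run_config: RunConfig, per_type: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Attach cluster labels, pooling events across animals per type.

    Event types with too few events for a k-cluster fit keep an empty
    label.  Returns the labelled table and the fitted models (as
    JSON-ready dicts keyed by event type).
    """
    events = events.copy()
    events["cluster_label"] = ""
    models: dict[str, dict] = {}
    type_groups = events.groupby("type") if per_type else [("all", events)]
    for etype, g in type_groups:
        pts = g[["r_1mm", "r_2mm"]].to_numpy(dtype=float)
        if len(pts) < 5 * run_config.cluster_k:
            continue
        model, labels = fit_clusters(
            pts,
            k=run_config.cluster_k,
            seed=run_config.cluster_seed,
            max_iter=run_config.cluster_max_iter,
            reg_eps=run_config.cluster_reg_eps,
            init=run_config.cluster_init,
        )
        names = [model.names.get(int(l), str(l)) for l in labels]
        events.loc[g.index, "cluster_label"] = names
        models[str(etype)] = model.to_dict()
    return events, models


def run_pipeline(
    out_dir: str | Path,
    seed: int,
    session_minutes: float = 5.0,
    weeks: int = 2,
    animals_per_group: int = 2,
    groups: tuple[str, ...] = ("epilepsy_control", "epilepsy_laser_cut_single"),
    cohort_config: CohortConfig | None = None,
    run_config: RunConfig | None = None,
) -> dict[str, Path]:
    """Full desk-scale pipeline; writes all report tables under out_dir.

    Returns the mapping of artifact name → path.  Deterministic in
    (arguments, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_config = cohort_config or CohortConfig(base_seed=seed)
    run_config = run_config or RunConfig(seed=seed, cluster_seed=seed)
    group_map = {
        g: [f"{g}_m{i}" for i in range(animals_per_group)] for g in groups
    }
    session_s = session_minutes * 60.0

    recordings, truth = simulate_cohort(
        cohort_config, group_map, weeks, seed, session_s
    )
    events = score_sessions(recordings, run_config)
    if len(events):
        events, models = cluster_event_table(events, run_config)
    else:
        models = {}
    summaries = summarize_cohort(events, session_days=session_s / 86400.0)

    paths = {}
    paths["ground_truth"] = write_tables(truth, out / "ground_truth.csv")
    paths["events"] = write_tables(events, out / "events.csv")
    for name in ("daily", "per_animal", "per_group", "cluster_fractions"):
        paths[name] = write_tables(summaries[name], out / f"{name}.csv")

    track_frames = []
    seiz = events[events["type"] == "seizure"] if len(events) else events
    if len(seiz):
        for animal, g in seiz.groupby("animal_id"):
            t = weekly_track_table(
                weekly_track(g, min_seizures=run_config.weekly_min_seizures)
            )
            t.insert(0, "animal_id", animal)
            track_frames.append(t)
    tracks = (
        pd.concat(track_frames, ignore_index=True)
        if track_frames
        else pd.DataFrame()
    )
    paths["weekly_tracks"] = write_tables(tracks, out / "weekly_tracks.csv")

    manifest = {
        "version": __version__,
        "seed": seed,
        "session_minutes": session_minutes,
        "weeks": weeks,
        "groups": list(groups),
        "animals_per_group": animals_per_group,
        "cluster_models": models,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths
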