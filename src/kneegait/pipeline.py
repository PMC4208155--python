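"""Whole-session analysis: raw streams -> per-activity outcome metrics.

Stages: orientation fusion per sensor, anatomical calibration, knee and
pelvis angle series, per-annotation event detection and metrics.  The
result is a flat metric row per session (one column per parameter,
mirroring the outcome tables) plus the intermediate tables for
inspection.  Metrics whose activity is missing from the session are
absent (NaN), never zero; activities that are present but cannot be
analyzed are recorded as failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    SegmentFrames,
    estimate_gyro_bias,
    estimate_segment_frames,
    subtract_gyro_bias,
)
from .core import KneeAngleSeries, PelvisSeries, Session, ValidationError
from .events import (
    GaitEvents,
    detect_gait_events,
    detect_stair_steps,
    segment_strides,
    segment_tug,
)
from .fusion import FusionParams, detect_static, estimate_orientation
from .kinematics import knee_flexion_series, pelvis_series
from .metrics import (
    count_steps,
    fatigue_trend,
    knee_flexion_stats,
    power_metrics,
    spatiotemporal,
    stability_amplitude,
    symmetry_index,
    tug_metrics,
)

log = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "walking_speed", "cadence", "step_length", "symmetry_index",
    "max_knee_flexion_mean", "max_knee_flexion_min", "max_knee_flexion_max",
    "running_speed", "running_cadence",
    "stairs_time_per_step_up", "stairs_time_per_step_down",
    "stairs_max_flexion_up", "stairs_max_flexion_down",
    "stairs_flexion_at_heelstrike_down",
    "tug_sit_to_stand", "tug_stand_to_sit",
    "tug_max_transfer_flexion", "tug_evasive_excursion",
    "power_acceleration", "power_deceleration",
    "stability_coronal", "stability_sagittal",
    "fatigue_slope",
]


@dataclass
class SessionAnalysis:
    """Metric row plus intermediate products of one session."""

    metrics: dict
    frames: SegmentFrames
    knee: KneeAngleSeries
    pelvis: PelvisSeries
    stride_tables: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)
    tug_phases: pd.DataFrame | None = None
    failures: dict = field(default_factory=dict)


def analyze_session(
    session: Session,
    fusion: FusionParams | None = None,
    n_exclude: int = 2,
) -> SessionAnalysis:
    """Run the full pipeline on one session."""
    fusion = fusion or FusionParams()
    if session.calibration is None:
        raise ValidationError("session has no calibration captures")

    # the calibration captures double as zero-rate gyro references, refined
    # with static intervals detected in the session itself (protocol rests)
    bias = estimate_gyro_bias(session.calibration)
    cal_n = {
        s: sum(
            len(f[s])
            for f in [session.calibration.standing]
            + [p for _, p in session.calibration.flexion_poses]
            if s in f
        )
        for s in session.streams
    }
    for s, st in session.streams.items():
        mask = detect_static(st, fusion)
        if mask.sum() >= 2 * st.rate:
            n = cal_n[s] + int(mask.sum())
            bias[s] = (bias[s] * cal_n[s] + st.gyro[mask].sum(axis=0)) / n
    streams = {
        s: subtract_gyro_bias(st, bias[s]) for s, st in session.streams.items()
    }
    tracks = {s: estimate_orientation(st, fusion) for s, st in streams.items()}
    frames = estimate_segment_frames(session.calibration, fusion)
    knee = knee_flexion_series(
        tracks["thigh"], tracks["shank"], frames,
        streams["thigh"], streams["shank"],
    )
    pelvis = pelvis_series(tracks["pelvis"], frames, streams["pelvis"])

    metrics: dict = {c: np.nan for c in METRIC_COLUMNS}
    out = SessionAnalysis(metrics=metrics, frames=frames, knee=knee, pelvis=pelvis)
    shank = streams["shank"]

    stairs_acc: dict[str, list[dict]] = {"stairs_up": [], "stairs_down": []}
    tug_rows: list[pd.DataFrame] = []
    fatigue_candidates: list = []

    for ann in session.annotations:
        key = f"{ann.label}#{ann.repetition}"
        try:
            if ann.label in ("walk", "warmup", "run"):
                events = detect_gait_events(shank, knee, ann, frames)
                table = segment_strides(events, knee, shank, frames, n_exclude)
                out.events[key] = events
                out.stride_tables[key] = table
                if ann.label == "walk":
                    st = spatiotemporal(ann, count_steps(pelvis, ann))
                    metrics["walking_speed"] = st["speed"]
                    metrics["cadence"] = st["cadence"]
                    metrics["step_length"] = st["step_length"]
                    metrics.update(
                        {f"max_knee_flexion_{k.split('_')[-1]}": v
                         for k, v in knee_flexion_stats(table).items()}
                    )
                    stab = stability_amplitude(table)
                    metrics["stability_coronal"] = stab["stability_coronal"]
                    metrics["stability_sagittal"] = stab["stability_sagittal"]
                    metrics["symmetry_index"] = symmetry_index(pelvis, ann)
                elif ann.label == "run":
                    st = spatiotemporal(ann, count_steps(pelvis, ann))
                    metrics["running_speed"] = st["speed"]
                    metrics["running_cadence"] = st["cadence"]
                if ann.label in ("walk", "warmup") and ann.duration >= 60.0:
                    fatigue_candidates.append((ann, events))
            elif ann.label in ("stairs_up", "stairs_down"):
                table = detect_stair_steps(shank, knee, ann, frames)
                out.stride_tables[key] = table
                inc = table[~table["excluded"]]
                stairs_acc[ann.label].append(
                    {
                        "time_per_step": inc["time_per_step"].mean(),
                        "max_flexion": inc["max_flexion"].mean(),
                        "flexion_at_hs": inc["flexion_at_hs"].mean(),
                    }
                )
            elif ann.label == "tug":
                tug_rows.append(segment_tug(pelvis, None, ann))
            elif ann.label == "sprint_stop":
                metrics.update(power_metrics(knee, ann, pelvis))
        except ValidationError as err:
            out.failures[key] = str(err)
            log.warning("%s: %s", key, err)

    for label, suffix in (("stairs_up", "up"), ("stairs_down", "down")):
        flights = stairs_acc[label]
        if flights:
            metrics[f"stairs_time_per_step_{suffix}"] = float(
                np.mean([f["time_per_step"] for f in flights])
            )
            metrics[f"stairs_max_flexion_{suffix}"] = float(
                np.mean([f["max_flexion"] for f in flights])
            )
            if label == "stairs_down":
                metrics["stairs_flexion_at_heelstrike_down"] = float(
                    np.mean([f["flexion_at_hs"] for f in flights])
                )

    if tug_rows:
        out.tug_phases = pd.concat(tug_rows, ignore_index=True)
        metrics.update(tug_metrics(out.tug_phases, knee, pelvis))

    if fatigue_candidates:
        ann, events = max(fatigue_candidates, key=lambda p: p[0].duration)
        try:
            metrics["fatigue_slope"] = fatigue_trend(pelvis, ann, events)
        except ValidationError as err:
            out.failures[f"fatigue:{ann.label}"] = str(err)

    return out


def metrics_frame(analyses: dict[tuple[str, str], SessionAnalysis]) -> pd.DataFrame:
    """Flat table of metric rows keyed by (subject_id, timepoint)."""
    rows = []
    for (subject_id, timepoint), a in analyses.items():
        row = {"subject_id": subject_id, "timepoint": timepoint}
        row.update(a.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
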