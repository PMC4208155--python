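"""Session-level simulation: calibration captures and the full test protocol.

The emulated protocol mirrors the clinical session: anatomical calibration
(three supine knee-flexion holds + 5 s upright standing), a 2-min warm-up
walk, three Timed-Up-and-Go repetitions, a 100-m walk, a 50-m run, a
maximum sprint with abrupt stop, and four flights of stairs up and down.
"""

from __future__ import annotations

import numpy as np

from ..core import Annotation, CalibrationSet, SITES, Session
from .imu import draw_biases, synthesize_imu
from .kinematics import SegmentKinematics, _assemble, generate_segment_kinematics
from .params import GaitParams, ProtocolParams
from .truth import ActivityTruth, GroundTruth

CALIBRATION_POSE_ANGLES = (0.0, 45.0, 90.0)

FULL_PROTOCOL = (
    ["warmup"] + ["tug"] * 3 + ["walk", "run", "sprint_stop"]
    + ["stairs_up", "stairs_down"] * 4
)


def protocol_activities(protocol: ProtocolParams) -> list[str]:
    """Activity sequence of the clinical protocol for this configuration."""
    return (
        ["warmup"]
        + ["tug"] * protocol.tug_repetitions
        + ["walk", "run", "sprint_stop"]
        + ["stairs_up", "stairs_down"] * protocol.stair_flights
    )


def _static_kinematics(
    protocol: ProtocolParams, duration: float, hip_deg: float, knee_deg: float,
) -> SegmentKinematics:
    rate = protocol.rate
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    z = np.zeros(n)
    pelvis_pos = np.tile([0.0, 0.0, protocol.mounts.pelvis_height], (n, 1))
    truth = ActivityTruth(label="rest")
    return _assemble(
        t, rate, z + hip_deg, z + knee_deg, z, z, z, z, z, pelvis_pos,
        protocol.mounts, (0.0, float(t[-1])), truth,
    )


def simulate_calibration(
    protocol: ProtocolParams,
    rng: np.random.Generator,
    biases: dict[str, np.ndarray],
    pose_angles: tuple[float, ...] = CALIBRATION_POSE_ANGLES,
) -> CalibrationSet:
    """Standing (5.5 s) plus three supine knee-flexion holds (3 s each)."""
    params = protocol.walk
    standing_kin = _static_kinematics(protocol, 5.5, 0.0, 0.0)
    standing, _ = synthesize_imu(standing_kin, protocol.mounts, params, rng, biases)
    poses = []
    for angle in pose_angles:
        kin = _static_kinematics(protocol, 3.0, 80.0, angle)
        frags, _ = synthesize_imu(kin, protocol.mounts, params, rng, biases)
        poses.append((float(angle), frags))  # all sensors keep recording
    return CalibrationSet(standing=standing, flexion_poses=poses)


def simulate_activity_session(
    protocol: ProtocolParams,
    activities: list[str] | tuple[str, ...] = ("walk",),
    seed: int = 0,
    subject_id: str = "sim",
    timepoint: str = "pre",
    side: str = "right",
    with_calibration: bool = True,
) -> tuple[Session, GroundTruth]:
    """Simulate a session containing the given activity sequence.

    Repetition indices count repeats of each label in order of appearance.
    Returns the raw session plus its ground truth.
    """
    rng = np.random.default_rng(seed)
    biases = draw_biases(protocol.walk, rng)
    calibration = (
        simulate_calibration(protocol, rng, biases) if with_calibration else None
    )

    reps: dict[str, int] = {}
    parts: list[tuple[SegmentKinematics, dict[str, np.ndarray], dict]] = []
    for label in activities:
        reps[label] = reps.get(label, 0) + 1
        kin = generate_segment_kinematics(
            label if label != "warmup" else "warmup",
            protocol.walk,
            protocol,
            rate=protocol.rate,
            duration=protocol.warmup_duration if label == "warmup" else None,
            repetition=reps[label],
        )
        streams, q_true = synthesize_imu(kin, protocol.mounts, protocol.walk, rng, biases)
        parts.append((kin, q_true, streams))

    dt = 1.0 / protocol.rate
    offset = 0.0
    t_all: list[np.ndarray] = []
    flex_all: list[np.ndarray] = []
    chan = {s: {"accel": [], "gyro": [], "mag": [], "q": []} for s in SITES}
    annotations: list[Annotation] = []
    truth = GroundTruth()
    for kin, q_true, streams in parts:
        t_all.append(kin.t + offset)
        flex_all.append(kin.knee_flexion_deg)
        for s in SITES:
            chan[s]["accel"].append(streams[s].accel)
            chan[s]["gyro"].append(streams[s].gyro)
            chan[s]["mag"].append(streams[s].mag)
            chan[s]["q"].append(q_true[s])
        at = kin.truth
        shifted = ActivityTruth(
            label=at.label,
            repetition=at.repetition,
            heel_strikes=None if at.heel_strikes is None else at.heel_strikes + offset,
            toe_offs=None if at.toe_offs is None else at.toe_offs + offset,
            contacts=None if at.contacts is None else at.contacts + offset,
            transitions=[(a + offset, b + offset) for a, b in at.transitions],
            params={
                k: (v + offset if k in ("peak_speed_time", "stop_onset") else v)
                for k, v in at.params.items()
            },
        )
        truth.activities.append(shifted)
        annotations.append(
            Annotation(
                label=at.label,
                t_start=kin.core[0] + offset,
                t_end=kin.core[1] + offset,
                path_length=at.params.get("path_length"),
                repetition=at.repetition,
            )
        )
        offset += kin.t[-1] + dt

    t = np.concatenate(t_all)
    from ..quat import enforce_continuity

    sess_streams = {}
    for s in SITES:
        from ..core import SensorStream

        sess_streams[s] = SensorStream(
            site=s,
            t=t,
            accel=np.vstack(chan[s]["accel"]),
            gyro=np.vstack(chan[s]["gyro"]),
            mag=np.vstack(chan[s]["mag"]),
            rate=protocol.rate,
        )
        truth.orientations[s] = (t, enforce_continuity(np.vstack(chan[s]["q"])))
    truth.knee_flexion = (t, np.concatenate(flex_all))

    session = Session(
        subject_id=subject_id,
        timepoint=timepoint,
        side=side,
        streams=sess_streams,
        annotations=annotations,
        calibration=calibration,
    )
    return session, truth


def simulate_protocol(
    params_pre: ProtocolParams,
    params_post: ProtocolParams,
    seed: int = 0,
    subject_id: str = "sim",
) -> tuple[Session, Session, tuple[GroundTruth, GroundTruth]]:
    """Two full annotated sessions (pre and post surgery) with ground truth."""
    pre, gt_pre = simulate_activity_session(
        params_pre, protocol_activities(params_pre), seed=seed,
        subject_id=subject_id, timepoint="pre",
    )
    post, gt_post = simulate_activity_session(
        params_post, protocol_activities(params_post), seed=seed + 1,
        subject_id=subject_id, timepoint="post",
    )
    return pre, post, (gt_pre, gt_post)
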