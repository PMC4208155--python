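"""Sensor-to-segment anatomical calibration.

The knee flexion axis is estimated functionally: across the three supine
knee-flexion holds, the thigh-relative shank orientation rotates about the
(segment-fixed) flexion axis, so the pairwise relative rotations between
poses share one rotation axis — recovered by a least-squares principal
direction over their rotation vectors, expressed in the shank and thigh
sensor frames.  The 5-s upright standing capture defines zero flexion,
neutral pelvis tilt/obliquity, and the anatomical planes (mediolateral =
flexion axis projected to the horizontal; anteroposterior = mediolateral x
vertical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import CalibrationSet, OrientationTrack, SensorStream, ValidationError
from .fusion import FusionParams, estimate_orientation
from .quat import qconj, qmean, qmul, swing_twist_angle

QUASI_STATIC_GYRO_RMS = 0.05   # rad/s
MIN_PAIR_ANGLE_DEG = 20.0      # below this total spread the poses are degenerate
DEFAULT_POSE_ANGLES = (0.0, 45.0, 90.0)


@dataclass
class SegmentFrames:
    """Calibrated anatomical frames shared by the whole session."""

    q_stand: dict[str, np.ndarray]       # per-site standing sensor->world quat
    q_rel_stand: np.ndarray              # shank-sensor -> thigh-sensor at standing
    axis_shank: np.ndarray               # knee flexion axis, shank sensor frame
    axis_thigh: np.ndarray               # knee flexion axis, thigh sensor frame
    ml_world: np.ndarray                 # mediolateral axis, world frame
    ap_world: np.ndarray                 # anteroposterior axis, world frame
    ap_shank: np.ndarray                 # anteroposterior axis, shank sensor frame
    pose_angles_est: list[float] = field(default_factory=list)  # deg, vs standing


def estimate_gyro_bias(calibration: CalibrationSet) -> dict[str, np.ndarray]:
    """Per-sensor gyro bias from all quasi-static calibration captures.

    The standing capture and the supine flexion holds are all zero-rate
    references; pooling them (weighted by length) minimises the residual
    bias left after subtraction, which otherwise dominates orientation
    drift over multi-minute recordings.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    fragments = [calibration.standing] + [f for _, f in calibration.flexion_poses]
    for frags in fragments:
        for site, stream in frags.items():
            sums[site] = sums.get(site, 0.0) + stream.gyro.sum(axis=0)
            counts[site] = counts.get(site, 0) + len(stream)
    return {site: sums[site] / counts[site] for site in sums}


def subtract_gyro_bias(stream: SensorStream, bias: np.ndarray) -> SensorStream:
    """Copy of a stream with a fixed gyro bias removed."""
    return SensorStream(
        site=stream.site,
        t=stream.t.copy(),
        accel=stream.accel.copy(),
        gyro=stream.gyro - np.asarray(bias, float)[None, :],
        mag=stream.mag.copy(),
        rate=stream.rate,
    )


def _check_quasi_static(stream: SensorStream, what: str) -> None:
    rms = float(np.sqrt(np.mean(np.sum((stream.gyro - stream.gyro.mean(0)) ** 2, axis=1))))
    bias_mag = float(np.linalg.norm(stream.gyro.mean(0)))
    if rms + bias_mag > QUASI_STATIC_GYRO_RMS:
        raise ValidationError(
            f"{what} ({stream.site}) not quasi-static: gyro RMS "
            f"{rms + bias_mag:.3f} rad/s"
        )


def _static_pose_quat(stream: SensorStream, fusion: FusionParams) -> np.ndarray:
    """Mean orientation of a quasi-static fragment (init window discarded)."""
    track = estimate_orientation(stream, fusion)
    n_skip = int(round(fusion.init_window * stream.rate))
    return qmean(track.q[n_skip:])


def estimate_segment_frames(
    calibration: CalibrationSet,
    fusion: FusionParams | None = None,
) -> SegmentFrames:
    """Estimate anatomical frames from the calibration captures.

    Raises ``ValidationError`` when a fragment is not quasi-static or the
    three poses do not span enough flexion ("degenerate calibration").
    """
    fusion = fusion or FusionParams()

    for site, stream in calibration.standing.items():
        _check_quasi_static(stream, "standing capture")
    bias = estimate_gyro_bias(calibration)
    q_stand = {
        site: _static_pose_quat(subtract_gyro_bias(stream, bias[site]), fusion)
        for site, stream in calibration.standing.items()
    }

    poses = sorted(calibration.flexion_poses, key=lambda p: p[0])
    q_rel_poses = []
    for angle, frags in poses:
        for site in ("thigh", "shank"):
            _check_quasi_static(frags[site], f"flexion pose {angle:g} deg")
        qt = _static_pose_quat(subtract_gyro_bias(frags["thigh"], bias["thigh"]), fusion)
        qs = _static_pose_quat(subtract_gyro_bias(frags["shank"], bias["shank"]), fusion)
        q_rel_poses.append(qmul(qconj(qt), qs))

    # pairwise relative rotations between poses, ordered low -> high flexion
    vec_shank, vec_thigh = [], []
    max_angle = 0.0
    for i in range(len(q_rel_poses)):
        for j in range(i + 1, len(q_rel_poses)):
            a = qmul(qconj(q_rel_poses[i]), q_rel_poses[j])   # shank-frame axis
            b = qmul(q_rel_poses[j], qconj(q_rel_poses[i]))   # thigh-frame axis
            rv_a = Rotation.from_quat(a).as_rotvec()
            rv_b = Rotation.from_quat(b).as_rotvec()
            max_angle = max(max_angle, float(np.linalg.norm(rv_a)))
            vec_shank.append(rv_a)
            vec_thigh.append(rv_b)
    if np.degrees(max_angle) < MIN_PAIR_ANGLE_DEG:
        raise ValidationError("degenerate calibration: poses span too little flexion")

    def principal(vecs: list[np.ndarray]) -> np.ndarray:
        m = np.asarray(vecs)
        _, _, vt = np.linalg.svd(m, full_matrices=False)
        axis = vt[0]
        if np.sum(m @ axis) < 0:  # flexion increases low -> high pose
            axis = -axis
        return axis / np.linalg.norm(axis)

    axis_shank = principal(vec_shank)
    axis_thigh = principal(vec_thigh)

    q_rel_stand = qmul(qconj(q_stand["thigh"]), q_stand["shank"])
    pose_angles_est = [
        float(
            np.degrees(
                swing_twist_angle(qmul(qconj(q_rel_stand), q), axis_shank)
            )
        )
        for q in q_rel_poses
    ]

    # anatomical planes from the flexion axis and the world vertical
    ml = Rotation.from_quat(q_stand["shank"]).apply(axis_shank)
    ml = ml - ml[2] * np.array([0.0, 0.0, 1.0])
    nml = np.linalg.norm(ml)
    if nml < 1e-6:
        raise ValidationError("degenerate calibration: flexion axis near vertical")
    ml /= nml
    ap = np.cross(ml, [0.0, 0.0, 1.0])
    ap_shank = Rotation.from_quat(q_stand["shank"]).inv().apply(ap)

    return SegmentFrames(
        q_stand=q_stand,
        q_rel_stand=q_rel_stand,
        axis_shank=axis_shank,
        axis_thigh=axis_thigh,
        ml_world=ml,
        ap_world=ap,
        ap_shank=ap_shank,
        pose_angles_est=pose_angles_est,
    )
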