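"""Knee and pelvis angle series from calibrated orientation tracks.

Knee flexion is the swing-twist angle of the thigh-relative shank rotation
about the calibrated flexion axis, zeroed at the standing reference —
robust to ab/adduction cross-talk, unlike a full Euler sequence.  The knee
angular velocity is formed from the two gyroscopes resolved through the
orientation tracks (not by differentiating angles, which amplifies noise).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import SegmentFrames
from .core import (
    KneeAngleSeries,
    OrientationTrack,
    PelvisSeries,
    SensorStream,
    ValidationError,
)
from .quat import qconj, qmul, swing_twist_angle


def _common_support(
    a: OrientationTrack, b: OrientationTrack
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of the shared time base of two tracks (same rate, same clock)."""
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 <= t0:
        raise ValidationError("orientation tracks do not overlap in time")
    ia = np.searchsorted(a.t, t0 - 1e-9)
    ib = np.searchsorted(b.t, t0 - 1e-9)
    n = min(np.searchsorted(a.t, t1 + 1e-9) - ia, np.searchsorted(b.t, t1 + 1e-9) - ib)
    return a.t[ia : ia + n], np.arange(ia, ia + n), np.arange(ib, ib + n)


def knee_flexion_series(
    thigh_track: OrientationTrack,
    shank_track: OrientationTrack,
    frames: SegmentFrames,
    thigh_stream: SensorStream | None = None,
    shank_stream: SensorStream | None = None,
) -> KneeAngleSeries:
    """Knee flexion angle (deg) and relative angular velocity (rad/s).

    When the raw streams are supplied the angular velocity is taken from
    the gyroscopes (shank rate mapped into the thigh sensor frame minus the
    thigh rate); otherwise it is differenced from the relative orientation.
    """
    t, ia, ib = _common_support(thigh_track, shank_track)
    q_rel = qmul(qconj(thigh_track.q[ia]), shank_track.q[ib])
    dev = qmul(qconj(frames.q_rel_stand)[None, :], q_rel)
    flexion = np.degrees(swing_twist_angle(dev, frames.axis_shank))

    r_rel = Rotation.from_quat(q_rel)
    if thigh_stream is not None and shank_stream is not None:
        wt = thigh_stream.gyro[ia]
        ws = shank_stream.gyro[ib]
        omega = r_rel.apply(ws) - wt
    else:
        dt = float(np.median(np.diff(t)))
        inc = (r_rel[:-1].inv() * r_rel[1:]).as_rotvec() / dt
        omega = np.vstack([inc, inc[-1]])
    mag = np.linalg.norm(omega, axis=1)
    return KneeAngleSeries(
        t=t, flexion_deg=flexion, angular_velocity=omega, angular_velocity_mag=mag
    )


def pelvis_series(
    pelvis_track: OrientationTrack,
    frames: SegmentFrames,
    pelvis_stream: SensorStream | None = None,
) -> PelvisSeries:
    """Pelvis tilt (forward lean, +) and obliquity (sidewise bend) in degrees.

    The pelvis rotation relative to standing is expressed in the anatomical
    frame (x anteroposterior, y mediolateral, z up) and decomposed as
    intrinsic yaw-pitch-roll; pitch is the tilt and roll the obliquity, so
    both stay meaningful after the subject turns around (heading drops into
    the yaw component).
    """
    e = qmul(pelvis_track.q, qconj(frames.q_stand["pelvis"])[None, :])
    c = Rotation.from_matrix(
        np.column_stack([frames.ap_world, frames.ml_world, [0.0, 0.0, 1.0]])
    )
    e_an = c.inv() * Rotation.from_quat(e) * c
    _, tilt, obliquity = np.degrees(e_an.as_euler("ZYX")).T
    if pelvis_stream is not None:
        gm = np.linalg.norm(pelvis_stream.gyro[: len(pelvis_track.t)], axis=1)
    else:
        dt = float(np.median(np.diff(pelvis_track.t)))
        r = Rotation.from_quat(pelvis_track.q)
        inc = (r[:-1].inv() * r[1:]).as_rotvec() / dt
        gm = np.linalg.norm(np.vstack([inc, inc[-1]]), axis=1)
    return PelvisSeries(
        t=pelvis_track.t.copy(), tilt_deg=tilt, obliquity_deg=obliquity, gyro_mag=gm
    )
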