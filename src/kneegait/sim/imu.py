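"""Inverse sensor model: segment kinematics -> raw 9-DoF streams.

The gyroscope reports the body-frame rotation increment per sample
interval (zero-order-hold body rates), the accelerometer the specific
force (gravity reaction plus linear acceleration of the attachment point)
in the sensor frame, and the magnetometer a homogeneous Earth field with a
60 degree dip angle.  A fixed per-sensor gyro bias and white Gaussian
noise are added on top; everything is driven by a seeded generator so a
given seed reproduces the session bit for bit.
"""

from __future__ import annotations

import numpy as np

from ..core import GRAVITY, SITES, SensorStream
from ..quat import body_rates_from_quat, qmul
from .kinematics import SegmentKinematics
from .params import GaitParams, SensorMounts

MAG_DIP_DEG = 60.0
MAG_WORLD = np.array(
    [np.cos(np.deg2rad(MAG_DIP_DEG)), 0.0, -np.sin(np.deg2rad(MAG_DIP_DEG))]
)
G_WORLD = np.array([0.0, 0.0, -GRAVITY])


def sensor_orientations(
    kin: SegmentKinematics, mounts: SensorMounts
) -> dict[str, np.ndarray]:
    """True sensor->world quaternions (segment orientation x rigid mount)."""
    return {
        site: qmul(kin.q_seg[site], mounts.mount_quat(site)[None, :])
        for site in SITES
    }


def draw_biases(params: GaitParams, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Fixed gyro bias vector per sensor (random direction, set magnitude)."""
    out = {}
    for site in SITES:
        v = rng.normal(size=3)
        out[site] = params.gyro_bias * v / np.linalg.norm(v)
    return out


def synthesize_imu(
    kin: SegmentKinematics,
    mounts: SensorMounts,
    params: GaitParams,
    rng: np.random.Generator,
    biases: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, SensorStream], dict[str, np.ndarray]]:
    """Synthesize the three raw streams for one kinematic segment.

    Returns ``(streams, true_sensor_quats)``.  Pass the same ``biases``
    dict across segments of a session so the bias stays fixed per sensor.
    """
    from scipy.spatial.transform import Rotation

    dt = 1.0 / kin.rate
    q_sensor = sensor_orientations(kin, mounts)
    biases = biases if biases is not None else draw_biases(params, rng)
    streams: dict[str, SensorStream] = {}
    for site in SITES:
        rot = Rotation.from_quat(q_sensor[site])
        gyro = body_rates_from_quat(q_sensor[site], dt)
        vel = np.gradient(kin.pos[site], dt, axis=0)
        acc_w = np.gradient(vel, dt, axis=0)
        f_world = acc_w - G_WORLD
        accel = rot.inv().apply(f_world)
        mag = rot.inv().apply(MAG_WORLD)
        n = len(kin.t)
        gyro = gyro + biases[site] + rng.normal(0.0, params.noise_sd_gyro, (n, 3))
        accel = accel + rng.normal(0.0, params.noise_sd_accel, (n, 3))
        mag = mag + rng.normal(0.0, params.noise_sd_mag, (n, 3))
        streams[site] = SensorStream(
            site=site, t=kin.t.copy(), accel=accel, gyro=gyro, mag=mag, rate=kin.rate
        )
    return streams, q_sensor
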