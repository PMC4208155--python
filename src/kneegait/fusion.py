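"""Orientation estimation from accelerometer, gyroscope and magnetometer.

A gradient-descent complementary filter in the Madgwick style: the
gyroscope is integrated exactly (exponential map, zero-order-hold body
rates) and gradient-descent correction steps of bounded magnitude pull
the estimate toward the reference directions of gravity (accelerometer)
and the Earth magnetic field (magnetometer, unit-normalized, entering
through the reference-field trick so it chiefly constrains heading).

Corrections are scheduled by a static-interval detector that is
independent of the orientation estimate: within a short sliding window
the angular rate must stay small and the specific force must be steady
and close to 1 g.  During such truly quiet intervals (quiet standing,
protocol rests, foot-flat instants) the full accelerometer + magnetometer
correction applies at ``static_gain``; during movement only the
magnetometer correction applies (at ``gain``, and only below a moderate
angular rate), because the magnetometer is immune to linear acceleration
while the accelerometer is not.  Gyro integration alone carries the
estimate through dynamic phases.

With ``gain = 0`` the filter reduces exactly to closed-form gyro
integration.  Initialization assumes the first ``init_window`` seconds
are quasi-static (accelerometer gives tilt, magnetometer heading).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, sin, sqrt

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .core import GRAVITY, OrientationTrack, SensorStream, ValidationError
from .quat import enforce_continuity


@dataclass
class FusionParams:
    gain: float = 0.02            # magnetometer (dynamic) step magnitude, rad/s
    static_gain: float | None = None  # accel+mag step when static; default 10x gain
    init_window: float = 0.5      # quasi-static initialization, s
    gyro_gate: float = 1.5        # max |omega| for the dynamic mag correction, rad/s
    static_window: float = 0.25   # sliding window of the static detector, s
    static_gyro_max: float = 0.3  # rad/s, max |omega| within the window
    static_accel_std: float = 0.3  # m/s^2, max specific-force std within the window
    static_accel_tol_g: float = 0.1  # max ||mean a| - g| within the window
    use_mag: bool = True

    @property
    def effective_static_gain(self) -> float:
        return 10.0 * self.gain if self.static_gain is None else self.static_gain


def _triad_init(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Initial sensor->world rotation matrix rows from static accel + mag."""
    z = accel / np.linalg.norm(accel)
    m = mag / np.linalg.norm(mag)
    mh = m - (m @ z) * z
    nh = np.linalg.norm(mh)
    if nh < 1e-9:
        raise ValidationError("magnetic field parallel to gravity; cannot initialize")
    x = mh / nh
    y = np.cross(z, x)
    return np.array([x, y, z])  # rows: world axes in sensor frame -> R[sensor->world]


def detect_static(stream: SensorStream, params: FusionParams | None = None) -> np.ndarray:
    """Boolean mask of samples lying in a quasi-static window.

    Uses only raw signals (no orientation estimate): the windowed maximum
    angular rate, the windowed standard deviation of the specific force,
    and the windowed mean specific-force magnitude.
    """
    params = params or FusionParams()
    win = max(int(round(params.static_window * stream.rate)), 2)
    gm = np.linalg.norm(stream.gyro, axis=1)
    mean_a = uniform_filter1d(stream.accel, win, axis=0, mode="nearest")
    mean_a2 = uniform_filter1d(stream.accel**2, win, axis=0, mode="nearest")
    var = np.clip(mean_a2 - mean_a**2, 0.0, None).sum(axis=1)
    return (
        (maximum_filter1d(gm, win, mode="nearest") < params.static_gyro_max)
        & (np.sqrt(var) < params.static_accel_std)
        & (
            np.abs(np.linalg.norm(mean_a, axis=1) - GRAVITY)
            < params.static_accel_tol_g * GRAVITY
        )
    )


def estimate_orientation(
    stream: SensorStream, params: FusionParams | None = None
) -> OrientationTrack:
    """Estimate the sensor's orientation track (scalar-last quaternions)."""
    params = params or FusionParams()
    dt = 1.0 / stream.rate
    n_init = int(round(params.init_window * stream.rate))
    if len(stream) <= n_init:
        raise ValidationError("stream shorter than initialization window")

    rmat = _triad_init(
        stream.accel[:n_init].mean(axis=0), stream.mag[:n_init].mean(axis=0)
    )
    from scipy.spatial.transform import Rotation

    qx, qy, qz, qw = Rotation.from_matrix(rmat).as_quat()
    w, x, y, z = qw, qx, qy, qz

    beta = params.gain
    static = (
        detect_static(stream, params).tolist()
        if beta > 0.0
        else [False] * len(stream)
    )
    gyro = stream.gyro.tolist()
    accel = stream.accel.tolist()
    mag = stream.mag.tolist()
    n = len(stream)
    beta_static = params.effective_static_gain
    gyro_gate = params.gyro_gate
    use_mag = params.use_mag

    out = np.empty((n, 4))
    out[0] = (x, y, z, w)
    for k in range(1, n):
        gx, gy, gz = gyro[k - 1]
        # exact integration of the body-rate increment over [k-1, k]
        ang = sqrt(gx * gx + gy * gy + gz * gz) * dt
        if ang > 1e-12:
            s = sin(0.5 * ang) / (ang / dt)
            dw, dx, dy, dz = cos(0.5 * ang), gx * s, gy * s, gz * s
            w, x, y, z = (
                w * dw - x * dx - y * dy - z * dz,
                w * dx + x * dw + y * dz - z * dy,
                w * dy - x * dz + y * dw + z * dx,
                w * dz + x * dy - y * dx + z * dw,
            )

        is_static = static[k]
        if beta > 0.0 and (
            is_static or sqrt(gx * gx + gy * gy + gz * gz) <= gyro_gate
        ):
            gw = gx_ = gy_ = gz_ = 0.0
            have_term = False

            if is_static:
                ax, ay, az = accel[k]
                anorm = sqrt(ax * ax + ay * ay + az * az)
                if anorm > 1e-9:
                    ax, ay, az = ax / anorm, ay / anorm, az / anorm
                    # gravity term: f = R^T (0,0,1) - a_hat
                    v1 = 2.0 * (x * z - w * y)
                    v2 = 2.0 * (y * z + w * x)
                    v3 = 1.0 - 2.0 * (x * x + y * y)
                    f1, f2, f3 = v1 - ax, v2 - ay, v3 - az
                    gw = -2.0 * y * f1 + 2.0 * x * f2
                    gx_ = 2.0 * z * f1 + 2.0 * w * f2 - 4.0 * x * f3
                    gy_ = -2.0 * w * f1 + 2.0 * z * f2 - 4.0 * y * f3
                    gz_ = 2.0 * x * f1 + 2.0 * y * f2
                    have_term = True

            if use_mag:
                mx, my, mz = mag[k]
                mn = sqrt(mx * mx + my * my + mz * mz)
                if mn > 1e-12:
                    have_term = True
                    mx, my, mz = mx / mn, my / mn, mz / mn
                    # measured field rotated to world coordinates
                    ww, xx, yy, zz = w * w, x * x, y * y, z * z
                    hx = (
                        (ww + xx - yy - zz) * mx
                        + 2.0 * (x * y - w * z) * my
                        + 2.0 * (x * z + w * y) * mz
                    )
                    hy = (
                        2.0 * (x * y + w * z) * mx
                        + (ww - xx + yy - zz) * my
                        + 2.0 * (y * z - w * x) * mz
                    )
                    hz = (
                        2.0 * (x * z - w * y) * mx
                        + 2.0 * (y * z + w * x) * my
                        + (ww - xx - yy + zz) * mz
                    )
                    bx = sqrt(hx * hx + hy * hy)
                    bz = hz
                    # f_m = R^T (bx, 0, bz) - m_hat
                    u1 = bx * (1.0 - 2.0 * (yy + zz)) + 2.0 * bz * (x * z - w * y)
                    u2 = 2.0 * bx * (x * y - w * z) + 2.0 * bz * (y * z + w * x)
                    u3 = 2.0 * bx * (x * z + w * y) + bz * (1.0 - 2.0 * (xx + yy))
                    e1, e2, e3 = u1 - mx, u2 - my, u3 - mz
                    gw += (
                        -2.0 * bz * y * e1
                        + (-2.0 * bx * z + 2.0 * bz * x) * e2
                        + 2.0 * bx * y * e3
                    )
                    gx_ += (
                        2.0 * bz * z * e1
                        + (2.0 * bx * y + 2.0 * bz * w) * e2
                        + (2.0 * bx * z - 4.0 * bz * x) * e3
                    )
                    gy_ += (
                        (-4.0 * bx * y - 2.0 * bz * w) * e1
                        + (2.0 * bx * x + 2.0 * bz * z) * e2
                        + (2.0 * bx * w - 4.0 * bz * y) * e3
                    )
                    gz_ += (
                        (-4.0 * bx * z + 2.0 * bz * x) * e1
                        + (-2.0 * bx * w + 2.0 * bz * y) * e2
                        + 2.0 * bx * x * e3
                    )

            gn = sqrt(gw * gw + gx_ * gx_ + gy_ * gy_ + gz_ * gz_)
            if have_term and gn > 1e-12:
                step = (beta_static if is_static else beta) * dt / gn
                w -= step * gw
                x -= step * gx_
                y -= step * gy_
                z -= step * gz_

        norm = sqrt(w * w + x * x + y * y + z * z)
        w, x, y, z = w / norm, x / norm, y / norm, z / norm
        out[k] = (x, y, z, w)

    return OrientationTrack(site=stream.site, t=stream.t.copy(), q=enforce_continuity(out))
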