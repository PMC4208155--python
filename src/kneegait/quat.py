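"""Quaternion helpers shared across the pipeline.

Conventions
-----------
Quaternions are stored scalar-last ``(x, y, z, w)`` to interoperate with
:class:`scipy.spatial.transform.Rotation`, and always describe the rotation
*sensor frame -> world frame* unless noted otherwise.  The world frame is
z-up with x pointing along the horizontal component of the magnetic field
(magnetic north).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-last quaternion arrays (broadcasting)."""
    ax, ay, az, aw = np.moveaxis(np.asarray(a, float), -1, 0)
    bx, by, bz, bw = np.moveaxis(np.asarray(b, float), -1, 0)
    return np.stack(
        [
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
            aw * bw - ax * bx - ay * by - az * bz,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    out = q.copy()
    out[..., :3] *= -1.0
    return out


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` by quaternions ``q`` (sensor->world: body to world)."""
    return Rotation.from_quat(np.asarray(q, float)).apply(np.asarray(v, float))


def qexp(rotvec: np.ndarray) -> np.ndarray:
    """Unit quaternion of a rotation vector (axis * angle, radians)."""
    return Rotation.from_rotvec(np.atleast_2d(np.asarray(rotvec, float))).as_quat().squeeze()


def enforce_continuity(q: np.ndarray) -> np.ndarray:
    """Flip signs so consecutive quaternions stay in the same hemisphere."""
    q = np.asarray(q, float).copy()
    dots = np.sum(q[1:] * q[:-1], axis=-1)
    flips = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def qmean(q: np.ndarray) -> np.ndarray:
    """Chordal mean of a quaternion series (largest eigenvector of sum qq^T)."""
    q = np.asarray(q, float)
    m = q.T @ q
    vals, vecs = np.linalg.eigh(m)
    mean = vecs[:, -1]
    if mean[3] < 0:
        mean = -mean
    return mean / np.linalg.norm(mean)


def swing_twist_angle(q: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Signed twist angle (radians) of ``q`` about the unit ``axis``.

    Decomposes q = swing * twist with the twist a rotation about ``axis``;
    the returned angle lies in (-pi, pi].  Robust to rotation components
    orthogonal to the axis (ab/adduction cross-talk at the knee).
    """
    q = np.asarray(q, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    proj = q[..., :3] @ axis
    ang = 2.0 * np.arctan2(proj, q[..., 3])
    return np.mod(ang + np.pi, 2.0 * np.pi) - np.pi


def body_rates_from_quat(q: np.ndarray, dt: float) -> np.ndarray:
    """Body-frame angular velocity implied by a quaternion series.

    Uses the forward rotation increment per sample interval (a zero-order
    hold model of the gyroscope): ``w[k] = rotvec(q[k]^-1 q[k+1]) / dt``,
    with the final sample repeated.  Exact-inverse of exponential-map
    integration, which keeps simulator and filter self-consistent.
    """
    q = np.asarray(q, float)
    r = Rotation.from_quat(q)
    inc = (r[:-1].inv() * r[1:]).as_rotvec() / dt
    return np.vstack([inc, inc[-1]])


def integrate_body_rates(q0: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Closed-form (exponential map) integration of body rates from ``q0``."""
    inc = Rotation.from_rotvec(np.asarray(omega[:-1], float) * dt)
    out = [Rotation.from_quat(np.asarray(q0, float))]
    for r in inc:
        out.append(out[-1] * r)
    return enforce_continuity(Rotation.concatenate(out).as_quat())
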