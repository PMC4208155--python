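"""Core domain containers for three-sensor inertial gait sessions.

A recording session instruments the affected limb with three 9-DoF inertial
units (triaxial accelerometer + gyroscope + magnetometer): one on the
lumbosacral junction (``pelvis``), one on the lateral thigh and one on the
medial shank.  All angular rates are rad/s, accelerations m/s²,
magnetometer readings are unit-normalized on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

SITES = ("pelvis", "thigh", "shank")
ACTIVITY_LABELS = (
    "warmup",
    "tug",
    "walk",
    "run",
    "sprint_stop",
    "stairs_up",
    "stairs_down",
    "transfer",
    "rest",
)

GRAVITY = 9.81  # m/s^2


class ValidationError(ValueError):
    """A container violated its structural invariants."""


@dataclass
class SensorStream:
    """One sensor's timestamped 9-channel series (SI units)."""

    site: str
    t: np.ndarray          # seconds, strictly increasing
    accel: np.ndarray      # (N, 3) m/s^2, specific force
    gyro: np.ndarray       # (N, 3) rad/s
    mag: np.ndarray        # (N, 3) unit-normalized field direction
    rate: float            # Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        for name in ("accel", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape != (self.t.size, 3):
                raise ValidationError(
                    f"{name} shape {arr.shape} does not match {self.t.size} samples"
                )
        if self.site not in SITES:
            raise ValidationError(f"unknown sensor site {self.site!r}")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("non-monotonic time")
        if not self.rate > 0:
            raise ValidationError("rate must be positive")
        norms = np.linalg.norm(self.mag, axis=1)
        good = norms > 0
        self.mag = self.mag.copy()
        self.mag[good] /= norms[good, None]

    def __len__(self) -> int:
        return self.t.size

    def slice(self, t_start: float, t_end: float) -> "SensorStream":
        """Sub-stream covering [t_start, t_end] (inclusive of boundary samples)."""
        i = np.searchsorted(self.t, t_start, side="left")
        j = np.searchsorted(self.t, t_end, side="right")
        return SensorStream(
            self.site, self.t[i:j], self.accel[i:j], self.gyro[i:j],
            self.mag[i:j], self.rate,
        )


@dataclass
class Annotation:
    """A labeled activity interval; walk/run carry the surveyed path length."""

    label: str
    t_start: float
    t_end: float
    path_length: Optional[float] = None
    repetition: int = 1

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ValidationError(f"unknown activity label {self.label!r}")
        if not self.t_start < self.t_end:
            raise ValidationError("annotation requires t_start < t_end")
        if self.label in ("walk", "run") and self.path_length is None:
            raise ValidationError(f"{self.label} annotation requires path_length")
        if self.path_length is not None and not self.path_length > 0:
            raise ValidationError("path_length must be positive")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def check_non_overlapping(annotations: list[Annotation]) -> list[Annotation]:
    """Sort annotations and reject any overlap between intervals."""
    out = sorted(annotations, key=lambda a: a.t_start)
    for a, b in zip(out, out[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValidationError(
                f"overlapping annotations: {a.label}@{a.t_start:.2f}-{a.t_end:.2f} "
                f"and {b.label}@{b.t_start:.2f}-{b.t_end:.2f}"
            )
    return out


@dataclass
class CalibrationSet:
    """Anatomical calibration captures.

    ``standing``: >=5 s quasi-static upright stance (all three sensors).
    ``flexion_poses``: three quasi-static supine holds of the knee at
    distinct nominal flexion angles (thigh + shank sensors suffice, the
    pelvis fragment is carried when available).
    """

    standing: dict[str, SensorStream]
    flexion_poses: list[tuple[float, dict[str, SensorStream]]]

    def __post_init__(self) -> None:
        for site in ("thigh", "shank"):
            if site not in self.standing:
                raise ValidationError(f"standing capture missing {site} stream")
        if "pelvis" not in self.standing:
            raise ValidationError("standing capture missing pelvis stream")
        for angle, frags in self.flexion_poses:
            for site in ("thigh", "shank"):
                if site not in frags:
                    raise ValidationError(f"flexion pose at {angle} deg missing {site}")


@dataclass
class Session:
    """Three time-aligned streams + annotations + calibration + metadata."""

    subject_id: str
    timepoint: str                 # "pre" | "post"
    side: str                      # "left" | "right"
    streams: dict[str, SensorStream]
    annotations: list[Annotation] = field(default_factory=list)
    calibration: Optional[CalibrationSet] = None

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValidationError("timepoint must be 'pre' or 'post'")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        missing = [s for s in SITES if s not in self.streams]
        if missing:
            raise ValidationError(f"session missing sensor sites: {missing}")
        starts = [self.streams[s].t[0] for s in SITES]
        dt = 1.0 / max(self.streams[s].rate for s in SITES)
        if max(starts) - min(starts) > dt:
            raise ValidationError("streams not aligned to a common clock")
        self.annotations = check_non_overlapping(self.annotations)

    @property
    def rate(self) -> float:
        return self.streams["shank"].rate


@dataclass
class OrientationTrack:
    """Unit-quaternion series (sensor frame -> world), scalar-last order."""

    site: str
    t: np.ndarray
    q: np.ndarray  # (N, 4), (x, y, z, w)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.q = np.asarray(self.q, float)
        if self.q.shape != (self.t.size, 4):
            raise ValidationError("quaternion series shape mismatch")
        norms = np.linalg.norm(self.q, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("quaternions not unit norm")

    def slice(self, t_start: float, t_end: float) -> "OrientationTrack":
        i = np.searchsorted(self.t, t_start, side="left")
        j = np.searchsorted(self.t, t_end, side="right")
        return OrientationTrack(self.site, self.t[i:j], self.q[i:j])


@dataclass
class KneeAngleSeries:
    """Knee flexion angle and thigh-relative shank angular velocity."""

    t: np.ndarray
    flexion_deg: np.ndarray
    angular_velocity: np.ndarray       # (N, 3) rad/s, thigh-frame
    angular_velocity_mag: np.ndarray   # rad/s

    def slice(self, t_start: float, t_end: float) -> "KneeAngleSeries":
        m = (self.t >= t_start) & (self.t <= t_end)
        return KneeAngleSeries(
            self.t[m], self.flexion_deg[m],
            self.angular_velocity[m], self.angular_velocity_mag[m],
        )


@dataclass
class PelvisSeries:
    """Pelvis tilt/obliquity relative to the standing reference."""

    t: np.ndarray
    tilt_deg: np.ndarray        # sagittal lean, + forward
    obliquity_deg: np.ndarray   # sidewise bend
    gyro_mag: np.ndarray        # rad/s

    def slice(self, t_start: float, t_end: float) -> "PelvisSeries":
        m = (self.t >= t_start) & (self.t <= t_end)
        return PelvisSeries(
            self.t[m], self.tilt_deg[m], self.obliquity_deg[m], self.gyro_mag[m]
        )
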