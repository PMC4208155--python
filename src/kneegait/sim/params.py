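"""Simulation parameters.

Defaults emulate the clinical test protocol: a 2-min warm-up walk, three
Timed-Up-and-Go repetitions, a 100-m self-paced walk, a 50-m run, a maximum
sprint with an abrupt stop, and four flights of stairs (up and down).
Spatiotemporal defaults sit in the range observed in knee-arthroplasty
cohorts (walking ~1.2-1.5 m/s at 110-120 steps/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass
class GaitParams:
    """Stride-level gait model parameters for one cyclic activity.

    ``walking_speed`` must equal ``cadence / 60 * step_length``; passing
    ``None`` fills it in from the other two.
    """

    cadence: float = 116.0            # steps/min
    step_length: float = 0.70         # m
    walking_speed: float | None = None  # m/s
    max_knee_flexion_walk: float = 60.0  # deg, swing peak
    stance_knee_flexion: float = 15.0    # deg, stance bump
    stance_fraction: float = 0.6
    hip_amplitude_deg: float = 20.0
    pelvis_tilt_amp_deg: float = 3.0
    pelvis_obliquity_amp_deg: float = 4.0
    pelvis_yaw_amp_deg: float = 4.0
    bounce_amp_m: float = 0.02
    step_time_ratio: float = 1.0      # left/right step duration ratio (1 = symmetric)
    # sensor imperfections
    noise_sd_accel: float = 0.1       # m/s^2
    noise_sd_gyro: float = 0.01       # rad/s
    noise_sd_mag: float = 0.01        # unit field
    gyro_bias: float = 0.003          # rad/s, magnitude of a fixed per-sensor bias
    # pathology knobs
    instability_gain: float = 0.0     # scales coronal shank wobble in single support
    fatigue_slope: float = 0.0        # deg/min growth of pelvic evasive excursion
    seed: int = 0

    def __post_init__(self) -> None:
        implied = self.cadence / 60.0 * self.step_length
        if self.walking_speed is None:
            self.walking_speed = implied
        elif abs(self.walking_speed - implied) > 1e-9:
            raise ValueError(
                f"inconsistent parameters: speed {self.walking_speed} != "
                f"cadence/60 * step_length = {implied}"
            )
        for name in ("cadence", "step_length", "walking_speed", "stance_fraction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.4 <= self.stance_fraction <= 0.75:
            raise ValueError("stance_fraction outside plausible range [0.4, 0.75]")
        if self.step_time_ratio <= 0:
            raise ValueError("step_time_ratio must be positive")

    @property
    def stride_time(self) -> float:
        """Seconds per stride (two steps)."""
        return 120.0 / self.cadence

    def replace(self, **kw) -> "GaitParams":
        from dataclasses import replace

        if ("cadence" in kw or "step_length" in kw) and "walking_speed" not in kw:
            kw["walking_speed"] = None
        return replace(self, **kw)


@dataclass
class SensorMounts:
    """Rigid sensor-to-segment attachment model.

    Rotations map sensor axes into segment axes (the misalignment the
    anatomical calibration has to recover); lever arms locate the sensor on
    the segment.  Thigh and shank units sit 20 cm from the knee joint line.
    """

    pelvis_rotvec_deg: tuple = (0.0, 0.0, 5.0)
    thigh_rotvec_deg: tuple = (5.0, 0.0, 15.0)
    shank_rotvec_deg: tuple = (-5.0, 0.0, -10.0)
    thigh_length: float = 0.40       # hip -> knee, m
    shank_length: float = 0.40       # knee -> ankle, m
    sensor_offset_from_knee: float = 0.20  # m along each segment
    pelvis_height: float = 0.95      # standing hip height, m
    hip_offset: tuple = (0.0, 0.08, -0.08)  # hip centre in pelvis frame, m

    def mount_quat(self, site: str) -> np.ndarray:
        rv = {
            "pelvis": self.pelvis_rotvec_deg,
            "thigh": self.thigh_rotvec_deg,
            "shank": self.shank_rotvec_deg,
        }[site]
        return Rotation.from_rotvec(np.deg2rad(rv)).as_quat()


@dataclass
class ProtocolParams:
    """Full test-protocol configuration (one subject, one timepoint)."""

    walk: GaitParams = field(default_factory=GaitParams)
    walk_path_length: float = 100.0   # m
    warmup_duration: float = 120.0    # s

    # run (50 m as fast as possible)
    run_cadence: float = 160.0        # steps/min
    running_speed: float = 2.0        # m/s
    run_max_flexion: float = 70.0     # deg
    run_path_length: float = 50.0     # m

    # sprint with abrupt stop
    sprint_max_cadence: float = 170.0
    sprint_ramp_s: float = 3.0
    sprint_hold_s: float = 2.0
    stop_window_s: float = 0.5
    stop_flexion_deg: float = 45.0

    # stairs: four flights up + down, alternating feet
    stair_time_per_step: float = 0.5   # s per staircase step
    stair_steps_per_flight: int = 12
    stair_flights: int = 4
    stair_max_flexion_up: float = 80.0
    stair_max_flexion_down: float = 72.0
    stair_contact_flexion_up: float = 10.0
    stair_contact_flexion_down: float = 20.0
    stair_step_height: float = 0.17    # m
    stair_step_depth: float = 0.28     # m

    # Timed-Up-and-Go, three repetitions
    tug_repetitions: int = 3
    sit_to_stand_s: float = 2.2
    stand_to_sit_s: float = 2.5
    transfer_lean_deg: float = 8.0     # evasive pelvic excursion during transfers
    seated_flexion_deg: float = 90.0
    tug_walk_distance: float = 3.0     # m each way

    rate: float = 100.0                # Hz
    mounts: SensorMounts = field(default_factory=SensorMounts)

    @property
    def run_step_length(self) -> float:
        return 60.0 * self.running_speed / self.run_cadence

    def run_params(self) -> GaitParams:
        return self.walk.replace(
            cadence=self.run_cadence,
            step_length=self.run_step_length,
            max_knee_flexion_walk=self.run_max_flexion,
            hip_amplitude_deg=25.0,
            stance_fraction=0.45,
        )
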