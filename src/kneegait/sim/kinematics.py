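"""Parametric segment kinematics for the simulated activities.

Frames and sign conventions
---------------------------
World: z up, x along the (initial) direction of travel, y to the left
(mediolateral).  Segment orientations are segment->world rotations; the
standing pose is the identity for all three segments.  Hip flexion moves
the knee forward (rotation about -y); knee flexion folds the shank
backward relative to the thigh (rotation about +y), so the knee flexion
axis is +y in both segment frames and flexion is positive when the knee
bends.

The stride waveform is built from raised-cosine bumps: a small stance
flexion bump and a swing bump whose peak equals the configured maximum.
Activity segments begin and end in quiet standing, with C1 blending
envelopes, so concatenated segments remain smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .params import GaitParams, ProtocolParams, SensorMounts
from .truth import ActivityTruth

REST_S = 0.8     # quiet standing before/after each activity core
BLEND_S = 0.8    # C1 ramp of all oscillations into/out of the core
WOBBLE_HZ = 8.0  # instability wobble frequency
WOBBLE_BASE_DEG = 3.0  # coronal wobble amplitude at instability_gain = 1


@dataclass
class SegmentKinematics:
    """True segment trajectories of one activity (local time base)."""

    t: np.ndarray
    q_seg: dict[str, np.ndarray]    # site -> (N, 4) segment->world quats
    pos: dict[str, np.ndarray]      # site -> (N, 3) sensor positions, m
    core: tuple[float, float]       # annotated interval
    truth: ActivityTruth
    knee_flexion_deg: np.ndarray    # true joint angle series
    rate: float


def smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def raised_cosine(phi: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    d = phi - center
    return np.where(
        np.abs(d) < width / 2.0,
        0.5 * amp * (1.0 + np.cos(2.0 * np.pi * d / width)),
        0.0,
    )


def _warp_phase(phi: np.ndarray, ratio: float) -> np.ndarray:
    """Within-stride phase warp giving the two steps durations L:R = ratio."""
    frac = np.mod(phi, 1.0)
    base = np.floor(phi)
    dl = ratio / (1.0 + ratio)  # fraction of the stride spent on the first step
    first = frac < dl
    warped = np.where(first, 0.5 * frac / dl, 0.5 + 0.5 * (frac - dl) / (1.0 - dl))
    return base + warped


_SHANK_KNOTS_PHI = np.array([0.0, 0.06, 0.2, 0.32, 0.45, 0.6, 0.75, 0.9, 1.0])
_SHANK_KNOTS_DEG = np.array([12.0, 8.0, 7.5, 7.0, -12.0, -30.0, -45.0, -18.0, 12.0])
_shank_spline = None


def _shank_lean(phi: np.ndarray) -> np.ndarray:
    """Shank forward-lean (deg) over the stride: foot-flat plateau in early
    stance (the quiet window real sensor fusion relies on), forward tibia
    rotation through late stance, and a fast forward swing whose velocity
    peak precedes the heel strike at integer phase."""
    global _shank_spline
    if _shank_spline is None:
        from scipy.interpolate import CubicSpline

        # zero slope at the wrap puts the lean maximum (and with it the
        # detector's heel-strike zero crossing) exactly at integer phase
        _shank_spline = CubicSpline(
            _SHANK_KNOTS_PHI, _SHANK_KNOTS_DEG, bc_type=((1, 0.0), (1, 0.0))
        )
    return _shank_spline(np.mod(phi, 1.0))


def _knee_waveform(phi: np.ndarray, params: GaitParams) -> np.ndarray:
    """Level-gait knee flexion (deg) over stride phase [0, 1)."""
    f = np.mod(phi, 1.0)
    stance = raised_cosine(f, 0.2, 0.4, params.stance_knee_flexion)
    swing_c = (1.0 + params.stance_fraction) / 2.0
    swing = raised_cosine(f, swing_c, 0.4, params.max_knee_flexion_walk)
    return stance + swing


def _stair_waveform(phi: np.ndarray, contact_deg: float, max_deg: float) -> np.ndarray:
    """Stair knee flexion (deg): loaded at contact, swing peak at the maximum."""
    f = np.mod(phi, 1.0)
    base = contact_deg * np.cos(np.pi * f) ** 2
    amp = max_deg - 0.5 * contact_deg  # peak of base at phi=0.75 is contact/2
    return base + raised_cosine(f, 0.75, 0.4, amp)


def _assemble(
    t: np.ndarray,
    rate: float,
    hip_deg: np.ndarray,
    knee_deg: np.ndarray,
    wobble_deg: np.ndarray,
    pelvis_tilt_deg: np.ndarray,
    pelvis_roll_deg: np.ndarray,
    pelvis_yaw_deg: np.ndarray,
    heading_rad: np.ndarray,
    pelvis_pos: np.ndarray,
    mounts: SensorMounts,
    core: tuple[float, float],
    truth: ActivityTruth,
) -> SegmentKinematics:
    """Turn joint-angle channels into segment orientations and sensor positions."""
    head = Rotation.from_euler("z", np.reshape(heading_rad, (-1, 1)))
    r_pelvis = head * Rotation.from_euler(
        "ZYX",
        np.column_stack([
            np.deg2rad(pelvis_yaw_deg),
            np.deg2rad(pelvis_tilt_deg),
            np.deg2rad(pelvis_roll_deg),
        ]),
    )
    r_thigh = head * Rotation.from_euler("y", -np.deg2rad(np.reshape(hip_deg, (-1, 1))))
    r_shank = (
        r_thigh
        * Rotation.from_euler("y", np.deg2rad(np.reshape(knee_deg, (-1, 1))))
        * Rotation.from_euler("x", np.deg2rad(np.reshape(wobble_deg, (-1, 1))))
    )

    hip = pelvis_pos + r_pelvis.apply(np.asarray(mounts.hip_offset))
    knee = hip + r_thigh.apply([0.0, 0.0, -mounts.thigh_length])
    d = mounts.sensor_offset_from_knee
    pos = {
        "pelvis": pelvis_pos,
        "thigh": hip + r_thigh.apply([0.0, 0.0, -(mounts.thigh_length - d)]),
        "shank": knee + r_shank.apply([0.0, 0.0, -d]),
    }
    q_seg = {
        "pelvis": r_pelvis.as_quat(),
        "thigh": r_thigh.as_quat(),
        "shank": r_shank.as_quat(),
    }
    return SegmentKinematics(
        t=t, q_seg=q_seg, pos=pos, core=core, truth=truth,
        knee_flexion_deg=knee_deg, rate=rate,
    )


def _cyclic_gait(
    label: str,
    params: GaitParams,
    mounts: SensorMounts,
    rate: float,
    core_duration: float,
    *,
    waveform: str = "walk",
    contact_flexion: float = 0.0,
    max_flexion: float | None = None,
    climb_per_stride: float = 0.0,
    speed: float | None = None,
    path_length: float | None = None,
    repetition: int = 1,
) -> SegmentKinematics:
    """Shared builder for walk / run / stairs segments."""
    T = params.stride_time
    dt = 1.0 / rate
    n_core = int(round(core_duration * rate))
    core_duration = n_core * dt
    lead = REST_S + BLEND_S
    n = int(round((core_duration + 2 * lead) * rate)) + 1
    t = np.arange(n) * dt
    c0, c1 = lead, lead + core_duration
    env = smoothstep((t - REST_S) / BLEND_S) * smoothstep((c1 + BLEND_S - t) / BLEND_S)
    phi = (t - c0) / T
    wphi = _warp_phase(phi, params.step_time_ratio)
    t_core = np.clip(t - c0, 0.0, None)

    if waveform == "walk":
        knee = _knee_waveform(phi, params) * env
        # thigh = shank forward lean + knee flexion (hip flexion forward)
        hip = _shank_lean(phi) * env + knee
    else:
        knee = _stair_waveform(
            phi, contact_flexion, max_flexion or params.max_knee_flexion_walk
        ) * env
        hip = params.hip_amplitude_deg * np.cos(2 * np.pi * phi) * env

    window = raised_cosine(np.mod(phi, 1.0), 0.3, 0.4, 1.0)
    wobble_amp = params.instability_gain * WOBBLE_BASE_DEG
    wobble = wobble_amp * window * np.sin(2 * np.pi * WOBBLE_HZ * t) * env

    roll_amp = params.pelvis_obliquity_amp_deg + 0.5 * params.fatigue_slope * t_core / 60.0
    tilt = params.pelvis_tilt_amp_deg * np.sin(4 * np.pi * wphi) * env
    roll = roll_amp * np.sin(2 * np.pi * wphi) * env
    yaw = params.pelvis_yaw_amp_deg * np.sin(2 * np.pi * wphi) * env

    v_nom = params.walking_speed if speed is None else speed
    v = v_nom * env
    x = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    z = mounts.pelvis_height + params.bounce_amp_m * (np.cos(4 * np.pi * phi) - 1.0) * env / 2.0
    if climb_per_stride:
        climb_rate = climb_per_stride / T
        z = z + np.concatenate([[0.0], np.cumsum(0.5 * (env[1:] + env[:-1]) * dt)]) * climb_rate
    pelvis_pos = np.column_stack([x, np.zeros(n), z])

    n_strides = int(np.floor(core_duration / T + 1e-9))
    hs = c0 + np.arange(n_strides + 1) * T
    hs = hs[hs <= c1 + 1e-9]
    to = hs[:-1] + params.stance_fraction * T
    contacts = c0 + np.arange(int(np.floor(core_duration / (T / 2) + 1e-9)) + 1) * (T / 2)
    contacts = contacts[contacts <= c1 + 1e-9]

    ratio = params.step_time_ratio
    truth = ActivityTruth(
        label=label,
        repetition=repetition,
        heel_strikes=hs,
        toe_offs=to,
        contacts=contacts,
        params={
            "cadence": params.cadence,
            "speed": v_nom,
            "step_length": params.step_length if waveform == "walk" else np.nan,
            "path_length": path_length,
            "max_flexion": max_flexion or params.max_knee_flexion_walk,
            "contact_flexion": contact_flexion,
            "time_per_step": T / 2.0,
            "symmetry": min(ratio, 1.0 / ratio),
            "fatigue_slope": params.fatigue_slope,
            "coronal_wobble_peak": np.deg2rad(wobble_amp) * 2 * np.pi * WOBBLE_HZ,
        },
    )
    return _assemble(
        t, rate, hip, knee, wobble, tilt, roll, yaw, np.zeros(n), pelvis_pos,
        mounts, (c0, c1), truth,
    )


def _tug(
    protocol: ProtocolParams, params: GaitParams, mounts: SensorMounts,
    rate: float, repetition: int,
) -> SegmentKinematics:
    """One Timed-Up-and-Go repetition: sit->stand, walk out, turn, walk back,
    turn, stand->sit.  Pelvic tilt shows the configured evasive forward lean
    during both transfers (flat-topped bump with fast edges)."""
    dt = 1.0 / rate
    d_sts, d_stt = protocol.sit_to_stand_s, protocol.stand_to_sit_s
    v = 0.8 * params.walking_speed
    d_walk = protocol.tug_walk_distance / v
    d_turn = 1.2
    pause = 0.5
    rest = 1.0
    edge = 2.0  # unannotated sit-down / stand-up framing the repetition
    bounds = np.cumsum([
        0.5, edge,                                    # standing, sit down
        rest, d_sts, pause, d_walk, d_turn, d_walk, pause, d_turn, pause, d_stt,
        rest, edge, 0.5,                              # seated, stand up, standing
    ])
    (b_sd0, b_sd1, b_sts0, b_sts1, b_w0, b_w1, b_t1, b_w2, b_p2, b_t2,
     b_stt0, b_stt1, b_su0, b_su1, b_end) = bounds
    n = int(round(b_end * rate)) + 1
    t = np.arange(n) * dt

    def seg(a, b):
        return np.clip((t - a) / max(b - a, 1e-9), 0.0, 1.0)

    def up(t0, w):
        return smoothstep((t - t0) / w)

    def down(t1, w):
        return smoothstep((t1 - t) / w)

    # stance state: 0 seated, 1 standing; segments start and end standing
    stand = (
        1.0
        - smoothstep(seg(b_sd0, b_sd1))
        + smoothstep(seg(b_sts0, b_sts1))
        - smoothstep(seg(b_stt0, b_stt1))
        + smoothstep(seg(b_su0, b_su1))
    )
    hip = 90.0 * (1.0 - stand)
    knee = protocol.seated_flexion_deg * (1.0 - stand)

    # evasive forward lean during each transfer: flat-topped C1 bump
    f = 0.06

    def edgebump(a, b):
        tau = seg(a, b)
        return smoothstep(tau / f) * smoothstep((1.0 - tau) / f)

    tilt = protocol.transfer_lean_deg * (edgebump(b_sts0, b_sts1) + edgebump(b_stt0, b_stt1))

    # gait oscillation during the walk phases
    walk_env = up(b_w0, 0.4) * down(b_w1, 0.4) + up(b_t1, 0.4) * down(b_w2, 0.4)
    walk_env = np.clip(walk_env, 0.0, 1.0) * stand
    phi = np.concatenate([[0.0], np.cumsum(np.full(n - 1, dt))]) / params.stride_time
    hip = hip + 0.6 * params.hip_amplitude_deg * np.cos(2 * np.pi * phi) * walk_env
    knee = knee + 0.8 * _knee_waveform(phi, params) * walk_env
    roll = params.pelvis_obliquity_amp_deg * np.sin(2 * np.pi * phi) * walk_env
    tilt = tilt + params.pelvis_tilt_amp_deg * np.sin(4 * np.pi * phi) * walk_env

    heading = np.pi * (smoothstep(seg(b_w1, b_t1)) + smoothstep(seg(b_p2, b_t2)))

    speed = v * np.clip(
        up(b_w0, 0.4) * down(b_w1, 0.4) + up(b_t1, 0.4) * down(b_w2, 0.4), 0.0, 1.0
    )
    vx = speed * np.cos(heading)
    vy = speed * np.sin(heading)
    x = np.concatenate([[0.0], np.cumsum(0.5 * (vx[1:] + vx[:-1]) * dt)])
    y = np.concatenate([[0.0], np.cumsum(0.5 * (vy[1:] + vy[:-1]) * dt)])
    z = 0.55 + (mounts.pelvis_height - 0.55) * stand
    pelvis_pos = np.column_stack([x, y, z])

    truth = ActivityTruth(
        label="tug",
        repetition=repetition,
        transitions=[(b_sts0, b_sts1), (b_stt0, b_stt1)],
        params={
            "sit_to_stand": d_sts,
            "stand_to_sit": d_stt,
            "max_transfer_flexion": protocol.seated_flexion_deg,
            "evasive_excursion": protocol.transfer_lean_deg,
        },
    )
    return _assemble(
        t, rate, hip, knee, np.zeros(n), tilt, roll, np.zeros(n), heading,
        pelvis_pos, mounts, (b_sd1, b_su0), truth,
    )


def _sprint_stop(
    protocol: ProtocolParams, mounts: SensorMounts, rate: float
) -> SegmentKinematics:
    """Maximum-acceleration sprint ending in an abrupt stop.

    Cadence ramps to the sprint maximum, holds, then the gait oscillation
    collapses at a heel strike while a rapid stopping knee-flexion
    transient plays out over the configured stop window."""
    run = protocol.run_params().replace(cadence=protocol.sprint_max_cadence)
    dt = 1.0 / rate
    T = run.stride_time
    ramp, hold, stop_w = protocol.sprint_ramp_s, protocol.sprint_hold_s, protocol.stop_window_s
    lead = REST_S + BLEND_S

    # choose the stop onset at a heel strike (integer stride phase)
    def phase_at(tau):  # stride phase accumulated by local core time tau
        tt = np.arange(0.0, tau, dt)
        c = smoothstep(tt / ramp)
        return np.trapezoid(c, dx=dt) / T

    target = phase_at(ramp + hold)
    n_str = np.ceil(target)
    t_onset_core = ramp + hold + (n_str - target) * T  # extend hold to the next HS
    core_duration = t_onset_core + stop_w + 0.3
    n = int(round((core_duration + lead + REST_S + BLEND_S) * rate)) + 1
    t = np.arange(n) * dt
    c0 = lead
    tc = t - c0
    onset = c0 + t_onset_core

    cad_env = smoothstep(tc / ramp) * (1.0 - smoothstep((t - onset) / 0.2))
    phi = np.concatenate([[0.0], np.cumsum(0.5 * (cad_env[1:] + cad_env[:-1]) * dt)]) / T
    env = cad_env * smoothstep((t - REST_S) / BLEND_S)

    hip = run.hip_amplitude_deg * np.cos(2 * np.pi * phi) * env
    knee = _knee_waveform(phi, run) * env
    tau = np.clip((t - onset) / stop_w, 0.0, 1.0)
    knee = knee + protocol.stop_flexion_deg * np.sin(np.pi * tau) ** 2
    tilt = run.pelvis_tilt_amp_deg * np.sin(4 * np.pi * phi) * env
    roll = run.pelvis_obliquity_amp_deg * np.sin(2 * np.pi * phi) * env

    v = run.walking_speed * cad_env * (1.0 - smoothstep((t - onset) / stop_w))
    x = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * dt)])
    z = np.full(n, mounts.pelvis_height)
    pelvis_pos = np.column_stack([x, np.zeros(n), z])

    k_rate = np.gradient(np.deg2rad(knee), dt)
    in_acc = (t >= c0) & (t <= c0 + ramp)
    in_dec = (t >= onset) & (t <= onset + stop_w)
    truth = ActivityTruth(
        label="sprint_stop",
        params={
            "power_acceleration": float(np.max(np.abs(k_rate[in_acc]))),
            "power_deceleration": float(np.max(np.abs(k_rate[in_dec]))),
            "peak_speed_time": c0 + ramp,
            "stop_onset": onset,
        },
    )
    return _assemble(
        t, rate, hip, knee, np.zeros(n), tilt, roll, np.zeros(n), np.zeros(n),
        pelvis_pos, mounts, (c0, c0 + core_duration), truth,
    )


def generate_segment_kinematics(
    activity: str,
    params: GaitParams,
    protocol: ProtocolParams | None = None,
    *,
    rate: float = 100.0,
    duration: float | None = None,
    path_length: float | None = None,
    repetition: int = 1,
) -> SegmentKinematics:
    """Generate true segment trajectories + ground truth for one activity.

    ``params`` drives the stride model; stairs / TUG / sprint shapes come
    from ``protocol`` (defaults used when omitted).  For walk/run either a
    ``duration`` or a ``path_length`` fixes the core length.
    """
    protocol = protocol or ProtocolParams(walk=params)
    mounts = protocol.mounts
    if activity in ("walk", "warmup", "run"):
        p = protocol.run_params() if activity == "run" else params
        if duration is None:
            path = path_length if path_length is not None else (
                protocol.run_path_length if activity == "run" else protocol.walk_path_length
            )
            duration = path / p.walking_speed
        else:
            path = path_length
        return _cyclic_gait(
            activity, p, mounts, rate, duration, waveform="walk",
            path_length=path, repetition=repetition,
        )
    if activity in ("stairs_up", "stairs_down"):
        up = activity == "stairs_up"
        T_step = protocol.stair_time_per_step
        p = params.replace(
            cadence=120.0 / (2 * T_step),
            step_length=protocol.stair_step_depth,
            hip_amplitude_deg=25.0,
            stance_fraction=0.6,
        )
        n_strides = protocol.stair_steps_per_flight // 2
        climb = 2 * protocol.stair_step_height * (1.0 if up else -1.0)
        return _cyclic_gait(
            activity, p, mounts, rate, n_strides * p.stride_time,
            waveform="stairs",
            contact_flexion=(
                protocol.stair_contact_flexion_up if up
                else protocol.stair_contact_flexion_down
            ),
            max_flexion=(
                protocol.stair_max_flexion_up if up else protocol.stair_max_flexion_down
            ),
            climb_per_stride=climb,
            speed=2 * protocol.stair_step_depth / p.stride_time,
            repetition=repetition,
        )
    if activity == "tug":
        return _tug(protocol, params, mounts, rate, repetition)
    if activity == "sprint_stop":
        return _sprint_stop(protocol, mounts, rate)
    raise ValueError(f"unknown activity {activity!r}")
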