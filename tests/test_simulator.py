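import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kneegait.core import GRAVITY
from kneegait.quat import integrate_body_rates
from kneegait.sim import (
    GaitParams,
    ProtocolParams,
    SensorMounts,
    generate_segment_kinematics,
    simulate_activity_session,
    simulate_protocol,
    synthesize_imu,
)
from kneegait.sim.kinematics import _assemble
from kneegait.sim.protocol import FULL_PROTOCOL, _static_kinematics
from kneegait.sim.truth import ActivityTruth


class TestGaitParams:
    def test_speed_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GaitParams(cadence=120, step_length=0.75, walking_speed=2.0)

    def test_speed_derived(self):
        p = GaitParams(cadence=120, step_length=0.75)
        assert p.walking_speed == pytest.approx(1.5)


class TestKinematics:
    def test_walk_timing_arithmetic(self):
        p = GaitParams(cadence=120, step_length=0.75)
        kin = generate_segment_kinematics("walk", p, path_length=100.0)
        assert kin.truth.params["speed"] == pytest.approx(1.5)
        assert kin.core[1] - kin.core[0] == pytest.approx(100.0 / 1.5, abs=0.01)

    def test_max_flexion_is_configured_value(self):
        p = GaitParams(cadence=120, step_length=0.75, max_knee_flexion_walk=60.0)
        kin = generate_segment_kinematics("walk", p, duration=10.0)
        assert kin.knee_flexion_deg.max() == pytest.approx(60.0, abs=1e-6)

    def test_tug_transition_duration(self):
        p = GaitParams()
        protocol = ProtocolParams(walk=p, sit_to_stand_s=2.2)
        kin = generate_segment_kinematics("tug", p, protocol)
        (sts, _stt) = kin.truth.transitions
        assert sts[1] - sts[0] == pytest.approx(2.2)

    def test_true_events_inside_core(self):
        p = GaitParams(cadence=116, step_length=0.7)
        kin = generate_segment_kinematics("walk", p, duration=20.0)
        hs = kin.truth.heel_strikes
        assert hs.min() >= kin.core[0] - 1e-9
        assert hs.max() <= kin.core[1] + 1e-9

    def test_step_count_matches_cadence(self):
        p = GaitParams(cadence=116, step_length=0.7)
        kin = generate_segment_kinematics("walk", p, duration=30.0)
        n_steps = 2 * (len(kin.truth.heel_strikes) - 1)
        assert abs(n_steps - 116 / 60 * 30.0) <= 1.0


class TestSynthesizeImu:
    def test_static_gravity_and_zero_gyro(self, rng):
        protocol = ProtocolParams()
        kin = _static_kinematics(protocol, 2.0, 0.0, 0.0)
        p = GaitParams(noise_sd_accel=0, noise_sd_gyro=0, noise_sd_mag=0, gyro_bias=0)
        streams, _ = synthesize_imu(kin, SensorMounts(), p, rng)
        pel = streams["pelvis"]
        assert np.allclose(np.linalg.norm(pel.accel, axis=1), GRAVITY, atol=1e-6)
        assert np.allclose(pel.gyro, 0.0, atol=1e-9)

    def test_constant_rotation_rate(self, rng):
        n = 200
        t = np.arange(n) / 100.0
        yaw = np.deg2rad(90.0) * t  # 90 deg/s about world z
        kin = _assemble(
            t, 100.0, np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n),
            np.zeros(n), np.zeros(n), yaw,
            np.tile([0.0, 0.0, 0.95], (n, 1)),
            SensorMounts(pelvis_rotvec_deg=(0, 0, 0)),
            (0.0, t[-1]), ActivityTruth(label="rest"),
        )
        p = GaitParams(noise_sd_accel=0, noise_sd_gyro=0, noise_sd_mag=0, gyro_bias=0)
        streams, _ = synthesize_imu(kin, kin and SensorMounts(pelvis_rotvec_deg=(0, 0, 0)), p, rng)
        mags = np.linalg.norm(streams["pelvis"].gyro[:-1], axis=1)
        assert np.allclose(mags, np.pi / 2, atol=1e-9)

    def test_seed_reproducibility(self):
        p = ProtocolParams(walk=GaitParams(cadence=120, step_length=0.75))
        s1, _ = simulate_activity_session(p, ["walk"], seed=9)
        s2, _ = simulate_activity_session(p, ["walk"], seed=9)
        for site in ("pelvis", "thigh", "shank"):
            np.testing.assert_array_equal(
                s1.streams[site].accel, s2.streams[site].accel
            )
            np.testing.assert_array_equal(s1.streams[site].gyro, s2.streams[site].gyro)


class TestSelfConsistency:
    def test_noise_free_gyro_integrates_to_truth(self, quiet_walk_session):
        """Integrating the synthesized noise-free gyro recovers the true
        orientation within 0.5 degrees over the minute-long walk."""
        session, gt = quiet_walk_session
        for site in ("thigh", "shank"):
            stream = session.streams[site]
            _, q_true = gt.orientations[site]
            q = integrate_body_rates(q_true[0], stream.gyro, 1.0 / stream.rate)
            err = (Rotation.from_quat(q).inv() * Rotation.from_quat(q_true)).magnitude()
            assert np.degrees(err.max()) < 0.5

    def test_no_instability_means_quiet_coronal_channel(self, quiet_walk_session):
        """With instability off, the coronal shank rate during single-leg
        support stays below 5% of the sagittal amplitude."""
        session, gt = quiet_walk_session
        stream = session.streams["shank"]
        mounts = SensorMounts()
        ms = Rotation.from_rotvec(np.deg2rad(mounts.shank_rotvec_deg))
        ml = ms.inv().apply([0, 1, 0])
        ap = ms.inv().apply([1, 0, 0])
        sag_amp = np.abs(stream.gyro @ ml).max()
        truth = gt.activity("walk")
        cor_peaks = []
        for a, b in zip(truth.heel_strikes[:-1], truth.heel_strikes[1:]):
            m = (stream.t >= a + 0.12 * (b - a)) & (stream.t <= a + 0.48 * (b - a))
            cor_peaks.append(np.abs(stream.gyro[m] @ ap).max())
        assert np.median(cor_peaks) < 0.05 * sag_amp


class TestProtocol:
    def test_full_protocol_label_order(self):
        p = ProtocolParams(walk=GaitParams(cadence=120, step_length=0.75),
                           warmup_duration=20.0, stair_steps_per_flight=8)
        session, _ = simulate_activity_session(p, FULL_PROTOCOL, seed=2)
        labels = [a.label for a in session.annotations]
        assert labels == (
            ["warmup"] + ["tug"] * 3 + ["walk", "run", "sprint_stop"]
            + ["stairs_up", "stairs_down"] * 4
        )
        walk = next(a for a in session.annotations if a.label == "walk")
        run = next(a for a in session.annotations if a.label == "run")
        assert walk.path_length == pytest.approx(100.0)
        assert run.path_length == pytest.approx(50.0)
        reps = [a.repetition for a in session.annotations if a.label == "tug"]
        assert reps == [1, 2, 3]

    def test_streams_share_clock(self):
        p = ProtocolParams(walk=GaitParams(cadence=120, step_length=0.75))
        session, _ = simulate_activity_session(p, ["walk", "stairs_up"], seed=2)
        np.testing.assert_array_equal(session.streams["pelvis"].t, session.streams["shank"].t)

    def test_simulate_protocol_returns_pre_post_pair(self):
        pre = ProtocolParams(walk=GaitParams(cadence=114, step_length=60 * 1.5 / 114),
                             warmup_duration=10.0, stair_flights=1, tug_repetitions=1)
        post = ProtocolParams(walk=GaitParams(cadence=116, step_length=60 * 1.5 / 116),
                              warmup_duration=10.0, stair_flights=1, tug_repetitions=1)
        s_pre, s_post, (gt_pre, gt_post) = simulate_protocol(pre, post, seed=4)
        assert s_pre.timepoint == "pre" and s_post.timepoint == "post"
        assert gt_pre.activity("walk").params["cadence"] == 114
        assert gt_post.activity("walk").params["cadence"] == 116
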