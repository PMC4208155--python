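import numpy as np
import pytest

from kneegait.core import Annotation, ValidationError
from kneegait.events import (
    detect_gait_events,
    detect_stair_steps,
    segment_strides,
    segment_tug,
)
from kneegait.pipeline import analyze_session
from kneegait.sim import GaitParams, ProtocolParams, simulate_activity_session


def _walk_ann(session):
    return next(a for a in session.annotations if a.label == "walk")


class TestGaitEvents:
    def test_heel_strike_count_and_timing(self, walk_analysis, walk_session):
        """Each detected heel strike within 30 ms of a true one; count right."""
        _, gt = walk_session
        ev = walk_analysis.events["walk#1"]
        true_hs = gt.activity("walk").heel_strikes
        assert abs(len(ev.heel_strikes) - len(true_hs)) <= 1
        for h in ev.heel_strikes:
            assert np.min(np.abs(true_hs - h)) < 0.030

    def test_events_alternate(self, walk_analysis):
        ev = walk_analysis.events["walk#1"]
        for to in ev.toe_offs:
            assert np.any((ev.heel_strikes[:-1] < to) & (to < ev.heel_strikes[1:]))

    def test_static_interval_rejected(self, walk_session, walk_analysis):
        session, _ = walk_session
        ann = Annotation("walk", 0.0, 1.4, 2.0)  # lead-in rest only
        with pytest.raises(ValidationError, match="too short"):
            detect_gait_events(
                session.streams["shank"], walk_analysis.knee, ann, walk_analysis.frames
            )

    def test_run_stride_count(self):
        p = ProtocolParams(walk=GaitParams(cadence=120, step_length=0.75),
                           run_cadence=160.0, running_speed=2.5, run_path_length=40.0)
        session, gt = simulate_activity_session(p, ["run"], seed=13)
        a = analyze_session(session)
        ev = a.events["run#1"]
        true_hs = gt.activity("run").heel_strikes
        assert abs(len(ev.heel_strikes) - len(true_hs)) <= 1

    def test_noise_does_not_move_events(self):
        """Events shift by at most one sample between noise realizations."""
        p = ProtocolParams(walk=GaitParams(cadence=120, step_length=0.75),
                           walk_path_length=30.0)
        hs = []
        for seed in (31, 32):
            session, gt = simulate_activity_session(p, ["walk"], seed=seed)
            a = analyze_session(session)
            det = a.events["walk#1"].heel_strikes
            true_hs = gt.activity("walk").heel_strikes
            hs.append(np.array([det[np.argmin(np.abs(det - t))] for t in true_hs[1:-1]]))
        assert np.abs(hs[0] - hs[1]).max() <= 0.0101


class TestStrideTable:
    def test_exclusion_counts(self, walk_analysis):
        table = walk_analysis.stride_tables["walk#1"]
        n = len(table)
        assert (~table["excluded"]).sum() == n - 4

    def test_zero_exclusion(self, walk_analysis, walk_session):
        session, _ = walk_session
        ev = walk_analysis.events["walk#1"]
        table = segment_strides(
            ev, walk_analysis.knee, session.streams["shank"], walk_analysis.frames, 0
        )
        assert not table["excluded"].any()

    def test_durations_cover_annotation(self, walk_analysis, walk_session):
        session, _ = walk_session
        ann = _walk_ann(session)
        table = walk_analysis.stride_tables["walk#1"]
        total = table["duration"].sum()
        mean_stride = table["duration"].mean()
        assert abs(total - ann.duration) <= 2 * mean_stride


class TestStairs:
    def test_time_per_step_and_contact_flexion(self, mini_analysis, mini_protocol):
        protocol, _, gt = mini_protocol
        m = mini_analysis.metrics
        assert m["stairs_time_per_step_up"] == pytest.approx(
            protocol.stair_time_per_step, abs=0.02
        )
        assert m["stairs_time_per_step_down"] == pytest.approx(
            protocol.stair_time_per_step, abs=0.02
        )
        assert m["stairs_flexion_at_heelstrike_down"] == pytest.approx(
            protocol.stair_contact_flexion_down, abs=3.0
        )

    def test_flat_walk_flagged_low_confidence(self, walk_session, walk_analysis):
        """A stairs annotation over a level-walk signal has no stair-like
        loading at contact and is flagged."""
        session, _ = walk_session
        ann = _walk_ann(session)
        fake = Annotation("stairs_up", ann.t_start, ann.t_end, None, 1)
        table = detect_stair_steps(
            session.streams["shank"], walk_analysis.knee, fake, walk_analysis.frames
        )
        assert table.attrs["low_confidence"]

    def test_real_stairs_not_flagged(self, mini_analysis):
        assert not mini_analysis.stride_tables["stairs_down#1"].attrs["low_confidence"]


class TestTug:
    def test_three_repetitions_detected(self):
        p = ProtocolParams(walk=GaitParams(cadence=116, step_length=0.7),
                           tug_repetitions=3)
        session, _ = simulate_activity_session(p, ["tug", "tug", "tug"], seed=17)
        a = analyze_session(session)
        assert len(a.tug_phases) == 3
        assert a.tug_phases["repetition"].tolist() == [1, 2, 3]

    def test_transition_durations(self, mini_analysis, mini_protocol):
        protocol, _, _ = mini_protocol
        m = mini_analysis.metrics
        assert m["tug_sit_to_stand"] == pytest.approx(protocol.sit_to_stand_s, abs=0.15)
        assert m["tug_stand_to_sit"] == pytest.approx(protocol.stand_to_sit_s, abs=0.15)

    def test_flat_signal_rejected(self, walk_analysis):
        ann = Annotation("tug", 0.0, 1.4, None, 1)  # quiet lead-in
        with pytest.raises(ValidationError, match="excursion|short"):
            segment_tug(walk_analysis.pelvis, None, ann)

    def test_phases_contiguous(self, mini_analysis):
        row = mini_analysis.tug_phases.iloc[0]
        assert row.sts_start < row.sts_end <= row.turn_start < row.turn_end <= row.stt_start < row.stt_end
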