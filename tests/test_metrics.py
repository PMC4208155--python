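import numpy as np
import pytest

from kneegait.core import Annotation, KneeAngleSeries, ValidationError
from kneegait.metrics import (
    fatigue_trend,
    kmh_to_ms,
    knee_flexion_stats,
    spatiotemporal,
    stability_amplitude,
    symmetry_index,
    tug_metrics,
)
from kneegait.pipeline import analyze_session
from kneegait.sim import GaitParams, ProtocolParams, simulate_activity_session
import pandas as pd


def _stride_table(max_flexions, excluded_edges=0):
    n = len(max_flexions)
    return pd.DataFrame(
        {
            "start": np.arange(n, dtype=float),
            "end": np.arange(1, n + 1, dtype=float),
            "duration": np.ones(n),
            "max_flexion": max_flexions,
            "flexion_at_hs": np.zeros(n),
            "coronal_peak": np.full(n, 0.1),
            "sagittal_peak": np.full(n, 3.0),
            "excluded": [
                i < excluded_edges or i >= n - excluded_edges for i in range(n)
            ],
        }
    )


class TestSpatiotemporal:
    def test_worked_arithmetic(self):
        ann = Annotation("walk", 0.0, 66.67, 100.0)
        st = spatiotemporal(ann, 134)
        assert st["speed"] == pytest.approx(1.50, abs=0.005)
        assert st["cadence"] == pytest.approx(120.6, abs=0.1)
        assert st["step_length"] == pytest.approx(0.75, abs=0.005)

    def test_reference_patient_profile(self):
        """100 m at 1.5 m/s and cadence 114 implies 0.79 m steps (printed 0.8)."""
        ann = Annotation("walk", 0.0, 100 / 1.5, 100.0)
        steps = 114 / 60 * ann.duration
        st = spatiotemporal(ann, steps)
        assert st["step_length"] == pytest.approx(0.789, abs=0.001)
        assert round(st["step_length"], 1) == 0.8

    def test_missing_path_rejected(self):
        with pytest.raises(ValidationError, match="path_length"):
            spatiotemporal(Annotation("warmup", 0.0, 60.0), 100)

    def test_simulator_recovery_within_two_percent(self, mini_analysis, mini_protocol):
        protocol, _, gt = mini_protocol
        truth = gt.activity("walk").params
        m = mini_analysis.metrics
        assert m["walking_speed"] == pytest.approx(truth["speed"], rel=0.02)
        assert m["cadence"] == pytest.approx(truth["cadence"], abs=1.0)
        assert m["step_length"] == pytest.approx(truth["step_length"], rel=0.02)

    def test_internal_consistency(self, mini_analysis):
        m = mini_analysis.metrics
        assert abs(m["step_length"] - 60 * m["walking_speed"] / m["cadence"]) <= 0.05


class TestKneeFlexionStats:
    def test_constant_strides(self):
        stats = knee_flexion_stats(_stride_table([60.0] * 8))
        assert stats == {
            "max_flexion_mean": 60.0,
            "max_flexion_min": 60.0,
            "max_flexion_max": 60.0,
        }

    def test_cohort_like_range(self):
        values = np.linspace(44.0, 71.0, 10)
        stats = knee_flexion_stats(_stride_table(values))
        assert (stats["max_flexion_min"], stats["max_flexion_max"]) == (44.0, 71.0)

    def test_too_few_strides_rejected(self):
        with pytest.raises(ValidationError):
            knee_flexion_stats(_stride_table([60.0] * 6, excluded_edges=2))


class TestPower:
    def test_constant_angle_is_zero(self, mini_analysis):
        t = np.arange(500) / 100.0
        knee = KneeAngleSeries(t, np.full(t.size, 20.0), np.zeros((t.size, 3)), np.zeros(t.size))
        from kneegait.metrics import power_metrics

        ann = Annotation("sprint_stop", 0.0, 5.0)
        pelvis = mini_analysis.pelvis
        sub = pelvis.slice(0.0, 5.0)
        res = power_metrics(knee, ann, pelvis)
        assert res["power_acceleration"] == 0.0

    def test_sprint_recovery(self):
        p = ProtocolParams(walk=GaitParams(cadence=116, step_length=0.7))
        session, gt = simulate_activity_session(p, ["sprint_stop"], seed=19)
        a = analyze_session(session)
        truth = gt.activity("sprint_stop").params
        assert a.metrics["power_acceleration"] == pytest.approx(
            truth["power_acceleration"], rel=0.10
        )
        assert a.metrics["power_deceleration"] == pytest.approx(
            truth["power_deceleration"], rel=0.10
        )

    def test_absent_without_sprint(self, walk_analysis):
        assert np.isnan(walk_analysis.metrics["power_acceleration"])


class TestStability:
    def test_clean_gait_coronal_far_below_sagittal(self, walk_analysis):
        m = walk_analysis.metrics
        assert m["stability_coronal"] < 0.05 * m["stability_sagittal"]

    def test_doubling_gain_doubles_coronal(self):
        vals = {}
        for g in (1.0, 2.0):
            p = ProtocolParams(
                walk=GaitParams(cadence=120, step_length=0.75, instability_gain=g),
                walk_path_length=40.0,
            )
            session, _ = simulate_activity_session(p, ["walk"], seed=23)
            vals[g] = analyze_session(session).metrics["stability_coronal"]
        assert vals[2.0] / vals[1.0] == pytest.approx(2.0, rel=0.10)

    def test_units_mirror(self):
        table = _stride_table([60.0] * 8)
        res = stability_amplitude(table)
        assert res["stability_coronal_dps"] == pytest.approx(
            np.degrees(res["stability_coronal"])
        )


class TestSymmetry:
    def test_symmetric_gait_is_one(self, walk_analysis):
        assert walk_analysis.metrics["symmetry_index"] == pytest.approx(1.0, abs=0.02)

    def test_ten_percent_asymmetry(self):
        p = ProtocolParams(
            walk=GaitParams(cadence=120, step_length=0.75, step_time_ratio=1.0 / 0.9)
        )
        session, gt = simulate_activity_session(p, ["walk"], seed=29)
        a = analyze_session(session)
        assert a.metrics["symmetry_index"] == pytest.approx(0.90, abs=0.02)

    def test_too_few_steps_rejected(self, walk_analysis):
        with pytest.raises(ValidationError, match="steps"):
            symmetry_index(walk_analysis.pelvis, Annotation("walk", 0.0, 2.0, 3.0))


class TestFatigue:
    def test_null_slope_near_zero(self, walk_analysis, walk_session):
        assert abs(walk_analysis.metrics["fatigue_slope"]) < 0.5

    def test_configured_slope_recovered(self):
        p = ProtocolParams(
            walk=GaitParams(cadence=114, step_length=60 * 1.5 / 114, fatigue_slope=2.0)
        )
        session, _ = simulate_activity_session(p, ["walk"], seed=37)
        a = analyze_session(session)
        assert a.metrics["fatigue_slope"] == pytest.approx(2.0, abs=0.5)

    def test_short_interval_rejected(self, walk_analysis):
        ann = Annotation("walk", 2.0, 32.0, 40.0)
        with pytest.raises(ValidationError, match="60 s"):
            fatigue_trend(walk_analysis.pelvis, ann, walk_analysis.events["walk#1"])


class TestTugMetrics:
    def test_post_op_like_transitions(self):
        p = ProtocolParams(
            walk=GaitParams(cadence=116, step_length=0.7),
            sit_to_stand_s=1.7, stand_to_sit_s=1.9, tug_repetitions=3,
        )
        session, _ = simulate_activity_session(p, ["tug"] * 3, seed=41)
        a = analyze_session(session)
        assert a.metrics["tug_sit_to_stand"] == pytest.approx(1.7, abs=0.1)
        assert a.metrics["tug_stand_to_sit"] == pytest.approx(1.9, abs=0.15)

    def test_zero_reps_error(self, walk_analysis):
        with pytest.raises(ValidationError):
            tug_metrics(pd.DataFrame(), walk_analysis.knee, walk_analysis.pelvis)


def test_kmh_conversion():
    assert kmh_to_ms(10.0) == pytest.approx(2.78, abs=0.005)
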