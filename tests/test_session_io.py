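import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneegait.core import Annotation, ValidationError
from kneegait.session_io import (
    apply_report_rounding,
    read_annotations,
    read_scores,
    read_session,
    read_stream,
    round_half_away,
    write_annotations,
    write_report,
    write_session,
    write_stream,
)


def _stream_df(n=10, rate=100.0, t0=0.0):
    t = t0 + np.arange(n) / rate
    data = {"t": t}
    for i, c in enumerate(["ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]):
        data[c] = np.sin(0.1 * t + i)
    data["az"] += 9.81
    data["mx"] += 1.0
    return pd.DataFrame(data)


class TestReadStream:
    def test_well_formed_file(self, tmp_path):
        _stream_df(10).to_csv(tmp_path / "s.csv", index=False)
        stream = read_stream(tmp_path / "s.csv", "shank")
        assert len(stream) == 10
        assert stream.rate == pytest.approx(100.0)
        assert stream.site == "shank"

    def test_dropped_sample_interpolated_at_midpoint(self, tmp_path):
        df = _stream_df(1000)
        kept = df.drop(index=500).reset_index(drop=True)
        kept.to_csv(tmp_path / "s.csv", index=False)
        stream = read_stream(tmp_path / "s.csv", "thigh")
        assert len(stream) == 1000
        expected = 0.5 * (df.loc[499, "ax"] + df.loc[501, "ax"])
        assert stream.accel[500, 0] == pytest.approx(expected, abs=1e-9)

    def test_reversed_timestamps_rejected(self, tmp_path):
        df = _stream_df(10)
        df["t"] = df["t"].to_numpy()[::-1]
        df.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValidationError, match="non-monotonic time"):
            read_stream(tmp_path / "s.csv", "shank")

    def test_long_gap_rejected(self, tmp_path):
        df = _stream_df(1000)
        df = df.drop(index=range(500, 520)).reset_index(drop=True)
        df.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValidationError, match="gap"):
            read_stream(tmp_path / "s.csv", "shank")

    def test_deg_per_second_header_converted(self, tmp_path):
        df = _stream_df(10)
        df["gx"] = 90.0
        path = tmp_path / "s.csv"
        with open(path, "w") as fh:
            fh.write("# site: shank\n# gyro_units: deg/s\n")
            df.to_csv(fh, index=False)
        stream = read_stream(path)
        assert stream.gyro[:, 0] == pytest.approx(np.pi / 2)

    def test_roundtrip(self, tmp_path, walk_session):
        session, _ = walk_session
        orig = session.streams["shank"]
        write_stream(orig, tmp_path / "s.csv")
        back = read_stream(tmp_path / "s.csv")
        assert back.site == orig.site
        np.testing.assert_allclose(back.t, orig.t, atol=1e-9)
        np.testing.assert_allclose(back.gyro, orig.gyro, rtol=1e-9)
        np.testing.assert_allclose(back.mag, orig.mag, rtol=1e-6)


class TestAnnotations:
    def test_walk_with_path_length(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "label,t_start,t_end,path_length,repetition\nwalk,0,80,100,1\n"
        )
        anns = read_annotations(tmp_path / "a.csv")
        assert len(anns) == 1
        assert anns[0].path_length == 100.0

    def test_empty_file(self, tmp_path):
        (tmp_path / "a.csv").write_text("")
        assert read_annotations(tmp_path / "a.csv") == []

    def test_overlapping_rejected(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "label,t_start,t_end,path_length,repetition\n"
            "walk,0,80,100,1\nwalk,70,150,100,2\n"
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_annotations(tmp_path / "a.csv")

    def test_walk_without_path_rejected(self, tmp_path):
        (tmp_path / "a.csv").write_text(
            "label,t_start,t_end,path_length,repetition\nwalk,0,80,,1\n"
        )
        with pytest.raises(ValidationError, match="path_length"):
            read_annotations(tmp_path / "a.csv")

    def test_roundtrip(self, tmp_path):
        anns = [
            Annotation("warmup", 0.0, 120.0),
            Annotation("walk", 130.0, 196.7, 100.0),
            Annotation("tug", 200.0, 215.5, None, 2),
        ]
        write_annotations(anns, tmp_path / "a.csv")
        assert read_annotations(tmp_path / "a.csv") == anns


class TestScores:
    def test_out_of_range_rejected(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "subject_id,timepoint,kss,oks,ucla,satisfaction\n1,pre,120,20,7,\n"
        )
        with pytest.raises(ValidationError, match="kss"):
            read_scores(tmp_path / "s.csv")

    def test_valid_table(self, tmp_path):
        (tmp_path / "s.csv").write_text(
            "subject_id,timepoint,kss,oks,ucla,satisfaction\n"
            "1,pre,38,18,7,\n1,post,37,22,7,\n"
        )
        df = read_scores(tmp_path / "s.csv")
        assert len(df) == 2


class TestReports:
    def test_rounding_examples(self):
        assert round_half_away(1.4444, 2) == 1.44
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13

    @given(st.floats(-1e6, 1e6), st.integers(0, 4))
    def test_rounding_error_bounded(self, v, nd):
        assert abs(round_half_away(v, nd) - v) <= 0.5 * 10.0 ** (-nd) + 1e-9

    def test_deterministic_bytes(self, tmp_path):
        df = pd.DataFrame({"walking_speed": [1.4444], "cadence": [114.29]})
        write_report(df, tmp_path / "a.csv")
        write_report(df, tmp_path / "b.csv")
        a = (tmp_path / "a.csv").read_bytes()
        assert a == (tmp_path / "b.csv").read_bytes()
        assert b"1.44" in a

    def test_json_csv_consistent(self, tmp_path):
        df = pd.DataFrame({"tug_sit_to_stand": [2.216], "max_flexion": [59.7]})
        write_report(df, tmp_path / "r.csv")
        write_report(df, tmp_path / "r.json")
        rounded = apply_report_rounding(df)
        assert rounded.loc[0, "tug_sit_to_stand"] == 2.22
        assert rounded.loc[0, "max_flexion"] == 60.0


def test_session_roundtrip(tmp_path, walk_session):
    session, _ = walk_session
    manifest = write_session(session, tmp_path)
    back = read_session(manifest)
    assert back.subject_id == session.subject_id
    assert back.annotations == session.annotations
    assert set(back.streams) == {"pelvis", "thigh", "shank"}
    np.testing.assert_allclose(
        back.streams["shank"].gyro, session.streams["shank"].gyro, rtol=1e-9
    )
    assert back.calibration is not None
    assert len(back.calibration.flexion_poses) == 3
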