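"""Gait event, stair step and TUG phase detection.

Heel strikes are taken at the negative-going zero crossing of the sagittal
shank angular velocity (the gyroscope projected on the calibrated flexion
axis) that follows each prominent mid-swing peak; toe-offs at the last
positive-going crossing before the peak.  The rule is robust across
walking, running and stairs because the mid-swing forward rotation of the
shank dominates the signal at every speed.

Single-leg support of the instrumented limb is inferred without
contralateral sensors: contralateral toe-off and heel strike are assumed
at fixed stride fractions (12% and 48%), an approximation documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .calibration import SegmentFrames
from .core import (
    Annotation,
    KneeAngleSeries,
    PelvisSeries,
    SensorStream,
    ValidationError,
)

MIN_STRIDES = 4
LOWPASS_HZ = 6.0          # detection channel low-pass
PEAK_HEIGHT_FRAC = 0.45   # mid-swing peak threshold vs global max
MIN_STRIDE_S = 0.45       # refractory distance between mid-swing peaks
SLS_START_FRAC = 0.12     # contralateral toe-off, fraction of stride
SLS_END_FRAC = 0.48       # contralateral heel strike, fraction of stride
TILT_BAND_DEG = 2.0       # band around baseline bounding a transfer
MIN_TRANSFER_S = 0.8
STAIR_CONTACT_FLEXION_MIN = 8.0  # deg; below this a "stairs" interval is suspect


@dataclass
class GaitEvents:
    """Detected gait events within one annotated interval (seconds)."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    strides: list[tuple[float, float]] = field(default_factory=list)
    single_support: list[tuple[float, float]] = field(default_factory=list)


def _lowpass(x: np.ndarray, rate: float, cutoff: float = LOWPASS_HZ) -> np.ndarray:
    sos = signal.butter(2, cutoff / (rate / 2.0), output="sos")
    return signal.sosfiltfilt(sos, x)


def _zero_cross(t: np.ndarray, x: np.ndarray, i: int, j: int, direction: int):
    """First (direction=-1: downward) crossing of x in samples [i, j)."""
    seg = x[i:j]
    if direction < 0:
        hits = np.nonzero((seg[:-1] > 0) & (seg[1:] <= 0))[0]
    else:
        hits = np.nonzero((seg[:-1] < 0) & (seg[1:] >= 0))[0]
    if hits.size == 0:
        return None
    k = i + hits[0]
    frac = x[k] / (x[k] - x[k + 1]) if x[k] != x[k + 1] else 0.0
    return float(t[k] + frac * (t[k + 1] - t[k]))


def sagittal_shank_velocity(
    shank_stream: SensorStream, frames: SegmentFrames
) -> np.ndarray:
    """Shank angular velocity about the flexion axis, sign-oriented so the
    mid-swing forward swing is positive."""
    s = shank_stream.gyro @ frames.axis_shank
    s = _lowpass(s, shank_stream.rate)
    if abs(s.min()) > abs(s.max()):
        s = -s
    return s


def detect_gait_events(
    shank_stream: SensorStream,
    knee_series: KneeAngleSeries,
    annotation: Annotation,
    frames: SegmentFrames,
) -> GaitEvents:
    """Detect heel strikes / toe-offs inside a cyclic-gait annotation."""
    if annotation.label not in ("walk", "run", "warmup", "sprint_stop", "stairs_up", "stairs_down"):
        raise ValidationError(f"cannot detect gait events in {annotation.label!r}")
    sub = shank_stream.slice(annotation.t_start, annotation.t_end)
    if len(sub) < int(2 * MIN_STRIDES * shank_stream.rate * MIN_STRIDE_S):
        raise ValidationError("too short to analyze")
    s = sagittal_shank_velocity(sub, frames)
    smax = float(s.max())
    if smax <= 0.5:  # rad/s; no swing-like motion at all
        raise ValidationError("too short to analyze")
    peaks, _ = signal.find_peaks(
        s, height=PEAK_HEIGHT_FRAC * smax, distance=int(MIN_STRIDE_S * sub.rate)
    )
    hs: list[float] = []
    to: list[float] = []
    n = len(s)
    for k, p in enumerate(peaks):
        nxt = peaks[k + 1] if k + 1 < len(peaks) else n - 1
        t_hs = _zero_cross(sub.t, s, p, nxt + 1, -1)
        prev = peaks[k - 1] if k > 0 else 0
        up_hits = np.nonzero((s[prev:p][:-1] < 0) & (s[prev + 1 : p + 1][:-1] >= 0))[0]
        t_to = None
        if up_hits.size:
            i = prev + up_hits[-1]
            frac = s[i] / (s[i] - s[i + 1]) if s[i] != s[i + 1] else 0.0
            t_to = float(sub.t[i] + frac * (sub.t[i + 1] - sub.t[i]))
        if t_hs is not None:
            hs.append(t_hs)
            if t_to is not None:
                to.append(t_to)
    hs_arr = np.asarray(hs)
    if hs_arr.size < MIN_STRIDES + 1:
        raise ValidationError("too short to analyze")
    to_arr = np.asarray(to)
    # keep the alternation heel_strike < toe_off < next heel_strike
    to = to_arr[(to_arr > hs_arr[0]) & (to_arr < hs_arr[-1])].tolist()
    strides = list(zip(hs_arr[:-1], hs_arr[1:]))
    sls = [
        (a + SLS_START_FRAC * (b - a), a + SLS_END_FRAC * (b - a)) for a, b in strides
    ]
    return GaitEvents(
        heel_strikes=hs_arr,
        toe_offs=np.asarray(to),
        strides=strides,
        single_support=sls,
    )


def _stride_table(
    events: GaitEvents,
    knee_series: KneeAngleSeries,
    shank_stream: SensorStream,
    frames: SegmentFrames,
    n_exclude: int,
) -> pd.DataFrame:
    """Per-stride metrics; first/last ``n_exclude`` strides flagged excluded."""
    coronal = _lowpass(shank_stream.gyro @ frames.ap_shank, shank_stream.rate, 12.0)
    sagittal = _lowpass(shank_stream.gyro @ frames.axis_shank, shank_stream.rate, 12.0)
    rows = []
    n = len(events.strides)
    for i, ((a, b), (sa, sb)) in enumerate(zip(events.strides, events.single_support)):
        m = (knee_series.t >= a) & (knee_series.t <= b)
        msl = (shank_stream.t >= sa) & (shank_stream.t <= sb)
        rows.append(
            {
                "start": a,
                "end": b,
                "duration": b - a,
                "max_flexion": float(knee_series.flexion_deg[m].max()) if m.any() else np.nan,
                "flexion_at_hs": float(
                    np.interp(a, knee_series.t, knee_series.flexion_deg)
                ),
                "coronal_peak": float(np.abs(coronal[msl]).max()) if msl.any() else np.nan,
                "sagittal_peak": float(np.abs(sagittal[msl]).max()) if msl.any() else np.nan,
                "excluded": i < n_exclude or i >= n - n_exclude,
            }
        )
    return pd.DataFrame(rows)


def segment_strides(
    events: GaitEvents,
    knee_series: KneeAngleSeries,
    shank_stream: SensorStream,
    frames: SegmentFrames,
    n_exclude: int = 2,
) -> pd.DataFrame:
    """Stride table for level gait (initial/final strides flagged, not dropped)."""
    return _stride_table(events, knee_series, shank_stream, frames, n_exclude)


def detect_stair_steps(
    shank_stream: SensorStream,
    knee_series: KneeAngleSeries,
    annotation: Annotation,
    frames: SegmentFrames,
    n_exclude: int = 1,
) -> pd.DataFrame:
    """Stair-step table for one flight.

    Steps alternate feet, so the time per staircase step is half the
    interval between successive ipsilateral contacts.  A flight whose
    knee flexion at contact never shows stair-like loading is flagged
    low-confidence (``df.attrs['low_confidence']``).
    """
    if annotation.label not in ("stairs_up", "stairs_down"):
        raise ValidationError("not a stairs annotation")
    events = detect_gait_events(shank_stream, knee_series, annotation, frames)
    if 2 * len(events.strides) < 4:
        raise ValidationError("fewer than 4 stair steps detected")
    table = _stride_table(events, knee_series, shank_stream, frames, n_exclude)
    table["time_per_step"] = table["duration"] / 2.0
    included = table[~table["excluded"]]
    table.attrs["low_confidence"] = bool(
        included["flexion_at_hs"].median() < STAIR_CONTACT_FLEXION_MIN
    )
    return table


def segment_tug(
    pelvis_series: PelvisSeries,
    events: GaitEvents | None,
    annotation: Annotation,
) -> pd.DataFrame:
    """Phase boundaries of one TUG repetition.

    The sit-to-stand transfer is the first sustained excursion of pelvic
    tilt out of a 2 degree band around the seated baseline; stand-to-sit is
    the last.  The turn is located at the dominant pelvic angular-rate
    burst between the transfers; the walk phases fill the gaps.
    """
    if annotation.label != "tug":
        raise ValidationError("not a tug annotation")
    sub = pelvis_series.slice(annotation.t_start, annotation.t_end)
    if sub.t.size < 10:
        raise ValidationError("tug interval too short")
    rate = 1.0 / float(np.median(np.diff(sub.t)))
    tilt = _lowpass(sub.tilt_deg, rate, 4.0)
    baseline = float(np.median(tilt[: max(int(0.5 * rate), 2)]))
    out_of_band = np.abs(tilt - baseline) > TILT_BAND_DEG

    # contiguous out-of-band regions, long enough to be transfers
    idx = np.nonzero(np.diff(out_of_band.astype(int)))[0] + 1
    bounds = np.concatenate([[0], idx, [out_of_band.size]])
    regions = [
        (sub.t[a], sub.t[min(b, len(sub.t) - 1)])
        for a, b in zip(bounds[:-1], bounds[1:])
        if out_of_band[a] and (sub.t[min(b, len(sub.t) - 1)] - sub.t[a]) >= MIN_TRANSFER_S
    ]
    if not regions:
        raise ValidationError("no tilt excursion found in tug repetition")
    sts = regions[0]
    stt = regions[-1] if len(regions) > 1 else (np.nan, np.nan)

    # turn: dominant angular-rate burst between the transfers
    turn = (np.nan, np.nan)
    if np.isfinite(stt[0]):
        m = (sub.t > sts[1]) & (sub.t < stt[0])
        if m.any():
            gm = _lowpass(sub.gyro_mag, rate, 2.0)
            gseg = np.where(m, gm, 0.0)
            p = int(np.argmax(gseg))
            thresh = 0.5 * gseg[p]
            i = p
            while i > 0 and gseg[i - 1] > thresh and m[i - 1]:
                i -= 1
            j = p
            while j < len(gseg) - 1 and gseg[j + 1] > thresh and m[j + 1]:
                j += 1
            turn = (float(sub.t[i]), float(sub.t[j]))

    row = {
        "repetition": annotation.repetition,
        "sit_to_stand": sts[1] - sts[0],
        "stand_to_sit": stt[1] - stt[0] if np.isfinite(stt[0]) else np.nan,
        "sts_start": sts[0],
        "sts_end": sts[1],
        "turn_start": turn[0],
        "turn_end": turn[1],
        "stt_start": stt[0],
        "stt_end": stt[1],
        "walk_out": turn[0] - sts[1] if np.isfinite(turn[0]) else np.nan,
        "walk_back": stt[0] - turn[1] if np.isfinite(turn[1]) else np.nan,
    }
    return pd.DataFrame([row])
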