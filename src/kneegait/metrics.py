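"""Per-activity outcome parameters.

Spatiotemporal values are anchored to the surveyed path length of the walk
and run tests: speed = path / duration, cadence from the step count, step
length = path / steps, with steps counted from the pelvic obliquity
oscillation (two per stride).  Knee-specific parameters come from the
stride table and the knee angular-velocity series; the "power of
acceleration / deceleration" of the sprint test is defined here as the
peak knee angular-velocity magnitude within the acceleration and stopping
sub-windows of the sprint (the split is derived from the pelvic
angular-rate envelope, a proxy for forward speed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import Annotation, KneeAngleSeries, PelvisSeries, ValidationError
from .events import GaitEvents, _lowpass

MIN_INCLUDED_STRIDES = 4
FATIGUE_MIN_DURATION_S = 60.0


def kmh_to_ms(speed_kmh: float) -> float:
    """km/h -> m/s (10 km/h = 2.78 m/s, the cohort's fastest running pace)."""
    return speed_kmh / 3.6


# ---------------------------------------------------------------------------
# step counting & spatiotemporal parameters


def _obliquity_crossings(pelvis: PelvisSeries, t_start: float, t_end: float) -> np.ndarray:
    sub = pelvis.slice(t_start, t_end)
    if sub.t.size < 10:
        return np.array([])
    rate = 1.0 / float(np.median(np.diff(sub.t)))
    x = _lowpass(sub.obliquity_deg, rate, 5.0)
    # baseline via rolling mid-range: robust to the DC that an asymmetric
    # (time-warped) oscillation carries, unlike the mean, so step-timing
    # asymmetry is not washed out of the crossing times
    win = max(int(2.5 * rate), 3)
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    x = x - 0.5 * (maximum_filter1d(x, win) + minimum_filter1d(x, win))
    sgn = np.signbit(x[:-1]) != np.signbit(x[1:])
    idx = np.nonzero(sgn)[0]
    frac = x[idx] / (x[idx] - x[idx + 1])
    return sub.t[idx] + frac * (sub.t[idx + 1] - sub.t[idx])


def count_steps(pelvis: PelvisSeries, annotation: Annotation) -> float:
    """Steps inside the annotation from pelvic obliquity zero crossings
    (one crossing per step, two per stride).

    Returns a fractional count: the interval duration divided by the mean
    step period over the observed crossings, which avoids the +-1
    quantization of a raw crossing count at the interval edges.
    """
    cross = _obliquity_crossings(pelvis, annotation.t_start, annotation.t_end)
    if cross.size < 3:
        return float(cross.size)
    period = (cross[-1] - cross[0]) / (cross.size - 1)
    return float(annotation.duration / period)


def spatiotemporal(annotation: Annotation, step_count: float) -> dict[str, float]:
    """Speed, cadence and step length anchored to the surveyed path length."""
    if annotation.path_length is None:
        raise ValidationError(f"{annotation.label} annotation lacks path_length")
    if step_count < 2 * MIN_INCLUDED_STRIDES:
        raise ValidationError("too few steps for spatiotemporal parameters")
    duration = annotation.duration
    return {
        "speed": annotation.path_length / duration,
        "cadence": step_count / duration * 60.0,
        "step_length": annotation.path_length / step_count,
    }


def symmetry_index(pelvis: PelvisSeries, annotation: Annotation) -> float:
    """Step-time symmetry from alternating pelvic half-cycles.

    Ratio of the mean durations of odd vs even half-cycles, folded as
    ``min(r, 1/r)`` so 1.0 is perfectly symmetric.
    """
    cross = _obliquity_crossings(pelvis, annotation.t_start, annotation.t_end)
    if cross.size < 9:  # fewer than 8 steps
        raise ValidationError("too few steps for symmetry")
    d = np.diff(cross)
    a, b = np.mean(d[0::2]), np.mean(d[1::2])
    r = a / b
    return float(min(r, 1.0 / r))


# ---------------------------------------------------------------------------
# knee flexion statistics


def knee_flexion_stats(stride_table: pd.DataFrame) -> dict[str, float]:
    """Mean and min-max range of per-stride maximum flexion (included strides)."""
    inc = stride_table[~stride_table["excluded"]]
    if len(inc) < MIN_INCLUDED_STRIDES:
        raise ValidationError("fewer than 4 included strides")
    mx = inc["max_flexion"].to_numpy()
    return {
        "max_flexion_mean": float(np.mean(mx)),
        "max_flexion_min": float(np.min(mx)),
        "max_flexion_max": float(np.max(mx)),
    }


def stability_amplitude(stride_table: pd.DataFrame) -> dict[str, float]:
    """Median over included strides of the peak shank angular-velocity
    amplitude during single-leg support, per anatomical plane (rad/s, with
    deg/s copies mirroring the unitless published amplitudes)."""
    inc = stride_table[~stride_table["excluded"]]
    if inc.empty:
        raise ValidationError("no included strides")
    cor = float(inc["coronal_peak"].median())
    sag = float(inc["sagittal_peak"].median())
    return {
        "stability_coronal": cor,
        "stability_sagittal": sag,
        "stability_coronal_dps": float(np.degrees(cor)),
        "stability_sagittal_dps": float(np.degrees(sag)),
    }


# ---------------------------------------------------------------------------
# sprint power


def power_metrics(
    knee_series: KneeAngleSeries,
    annotation: Annotation,
    pelvis: PelvisSeries,
) -> dict[str, float]:
    """Peak knee angular-velocity magnitude in the sprint sub-windows.

    The acceleration window runs from the start of the sprint to the peak
    of the (smoothed) pelvic angular-rate envelope; the deceleration window
    from where that envelope last drops below 60% of its peak (the stop
    onset) to the end of the interval.
    """
    if annotation.label != "sprint_stop":
        raise ValidationError("power metrics require a sprint_stop annotation")
    sub_p = pelvis.slice(annotation.t_start, annotation.t_end)
    rate = 1.0 / float(np.median(np.diff(sub_p.t)))
    env = _lowpass(np.abs(sub_p.gyro_mag), rate, 1.5)
    p = int(np.argmax(env))
    t_peak = float(sub_p.t[p])
    above = np.nonzero(env >= 0.6 * env[p])[0]
    t_onset = float(sub_p.t[above[-1]])

    sub_k = knee_series.slice(annotation.t_start, annotation.t_end)
    acc = (sub_k.t >= annotation.t_start) & (sub_k.t <= t_peak)
    dec = sub_k.t >= t_onset
    return {
        "power_acceleration": float(sub_k.angular_velocity_mag[acc].max()) if acc.any() else np.nan,
        "power_deceleration": float(sub_k.angular_velocity_mag[dec].max()) if dec.any() else np.nan,
    }


# ---------------------------------------------------------------------------
# fatigue


def fatigue_trend(
    pelvis: PelvisSeries, annotation: Annotation, events: GaitEvents
) -> float:
    """Slope (deg/min) of per-stride evasive pelvic excursion over time.

    Excursion is the peak-to-peak obliquity plus peak-to-peak tilt within
    each stride; the slope is an ordinary least-squares fit against the
    stride mid-time.
    """
    if annotation.duration < FATIGUE_MIN_DURATION_S:
        raise ValidationError("walk interval shorter than 60 s")
    mids, exc = [], []
    for a, b in events.strides:
        m = (pelvis.t >= a) & (pelvis.t <= b)
        if not m.any():
            continue
        mids.append(0.5 * (a + b) / 60.0)  # minutes
        exc.append(float(np.ptp(pelvis.obliquity_deg[m]) + np.ptp(pelvis.tilt_deg[m])))
    if len(mids) < 10:
        raise ValidationError("too few strides for a fatigue trend")
    res = stats.linregress(mids, exc)
    return float(res.slope)


# ---------------------------------------------------------------------------
# TUG aggregation


def tug_metrics(
    tug_phases: pd.DataFrame,
    knee_series: KneeAngleSeries,
    pelvis: PelvisSeries,
) -> dict[str, float]:
    """Means over repetitions of transfer durations, max transfer knee
    flexion and peak pelvic evasive excursion."""
    if tug_phases.empty:
        raise ValidationError("no valid tug repetitions")
    max_flex, evasive = [], []
    for row in tug_phases.itertuples(index=False):
        for a, b in ((row.sts_start, row.sts_end), (row.stt_start, row.stt_end)):
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            mk = (knee_series.t >= a) & (knee_series.t <= b)
            mp = (pelvis.t >= a) & (pelvis.t <= b)
            if mk.any():
                max_flex.append(float(knee_series.flexion_deg[mk].max()))
            if mp.any():
                evasive.append(
                    float(
                        max(
                            np.abs(pelvis.tilt_deg[mp]).max(),
                            np.abs(pelvis.obliquity_deg[mp]).max(),
                        )
                    )
                )
    return {
        "tug_sit_to_stand": float(tug_phases["sit_to_stand"].mean()),
        "tug_stand_to_sit": float(tug_phases["stand_to_sit"].mean()),
        "tug_max_transfer_flexion": float(np.mean(max_flex)) if max_flex else np.nan,
        "tug_evasive_excursion": float(np.mean(evasive)) if evasive else np.nan,
    }
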