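"""Reading and writing sessions, annotations, scores and reports.

All on-disk formats are plain text.  A sensor stream is one CSV per site
with columns ``t,ax,ay,az,gx,gy,gz,mx,my,mz`` (SI units), optionally
preceded by ``# key: value`` metadata lines; ``# gyro_units: deg/s``
switches the gyroscope columns to degrees per second on disk (converted to
rad/s on load).  A session manifest is a small YAML file tying the stream
files, the annotation track and the calibration captures together.
"""

from __future__ import annotations

import json
import logging
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    Annotation,
    CalibrationSet,
    SensorStream,
    Session,
    ValidationError,
    check_non_overlapping,
)

log = logging.getLogger(__name__)

STREAM_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]
MAX_GAP_SAMPLES = 10        # longest run of missing samples bridged by interpolation
MAX_MISSING_FRACTION = 0.01
RATE_RANGE = (50.0, 512.0)  # plausible IMU sampling rates, Hz


# ---------------------------------------------------------------------------
# streams


def _read_header_meta(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta, skip


def read_stream(path: str | Path, site: Optional[str] = None) -> SensorStream:
    """Load and validate one sensor stream CSV.

    Gaps of up to :data:`MAX_GAP_SAMPLES` consecutive missing samples are
    filled by linear interpolation (logged); larger gaps, more than 1%
    missing overall, or non-monotonic timestamps are rejected.
    """
    path = Path(path)
    meta, skip = _read_header_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    missing_cols = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path.name}: missing columns {missing_cols}")
    site = site or meta.get("site")
    if site is None:
        raise ValidationError(f"{path.name}: sensor site not given in header or argument")

    t = df["t"].to_numpy(float)
    if t.size < 2:
        raise ValidationError(f"{path.name}: stream too short")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("non-monotonic time")

    data = df[STREAM_COLUMNS[1:]].to_numpy(float)
    if meta.get("gyro_units", "rad/s") in ("deg/s", "dps"):
        data[:, 3:6] = np.deg2rad(data[:, 3:6])

    dt = float(np.median(np.diff(t)))
    rate = 1.0 / dt
    if not RATE_RANGE[0] <= rate <= RATE_RANGE[1]:
        raise ValidationError(f"{path.name}: implausible sampling rate {rate:.1f} Hz")

    # gap policy: rebuild the uniform grid, linearly interpolate short gaps
    steps = np.rint(np.diff(t) / dt).astype(int)
    if np.any(steps > MAX_GAP_SAMPLES + 1):
        raise ValidationError(f"{path.name}: gap longer than {MAX_GAP_SAMPLES} samples")
    n_missing = int(np.sum(steps - 1))
    n_total = t.size + n_missing
    if n_missing > MAX_MISSING_FRACTION * n_total:
        raise ValidationError(
            f"{path.name}: {n_missing}/{n_total} samples missing (> "
            f"{MAX_MISSING_FRACTION:.0%})"
        )
    if n_missing:
        log.warning("%s: interpolated %d missing samples", path.name, n_missing)
        grid = t[0] + dt * np.arange(n_total)
        data = np.column_stack(
            [np.interp(grid, t, data[:, k]) for k in range(data.shape[1])]
        )
        t = grid

    return SensorStream(
        site=site, t=t, accel=data[:, 0:3], gyro=data[:, 3:6], mag=data[:, 6:9],
        rate=rate,
    )


def write_stream(stream: SensorStream, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.accel, stream.gyro, stream.mag]),
        columns=STREAM_COLUMNS,
    )
    with open(path, "w", newline="") as fh:
        fh.write(f"# site: {stream.site}\n")
        fh.write(f"# rate: {stream.rate:.10g}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[Annotation]:
    """Load the activity annotation track (sorted, non-overlapping)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    anns = []
    for row in df.itertuples(index=False):
        pl = getattr(row, "path_length", None)
        if pl is not None and (pl == "" or (isinstance(pl, float) and math.isnan(pl))):
            pl = None
        rep = getattr(row, "repetition", 1)
        rep = 1 if (isinstance(rep, float) and math.isnan(rep)) else int(rep)
        anns.append(
            Annotation(
                label=str(row.label),
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                path_length=None if pl is None else float(pl),
                repetition=rep,
            )
        )
    return check_non_overlapping(anns)


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    rows = [
        {
            "label": a.label,
            "t_start": a.t_start,
            "t_end": a.t_end,
            "path_length": "" if a.path_length is None else a.path_length,
            "repetition": a.repetition,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["label", "t_start", "t_end", "path_length", "repetition"]).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# clinical scores

SCORE_RANGES = {"kss": (0, 100), "oks": (0, 48), "ucla": (1, 10)}


def read_scores(path: str | Path) -> pd.DataFrame:
    """Clinical score table: subject_id,timepoint,kss,oks,ucla,satisfaction."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = ["subject_id", "timepoint", "kss", "oks"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"score table missing columns {missing}")
    for col, (lo, hi) in SCORE_RANGES.items():
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValidationError(f"{col} scores outside [{lo}, {hi}]")
    bad = set(df["timepoint"]) - {"pre", "post"}
    if bad:
        raise ValidationError(f"unknown timepoints {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# session manifests


def write_session(session: Session, outdir: str | Path) -> Path:
    """Write a full session (streams, annotations, calibration, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = f"{session.subject_id}_{session.timepoint}"
    manifest: dict = {
        "subject_id": session.subject_id,
        "timepoint": session.timepoint,
        "side": session.side,
        "streams": {},
    }
    for site, stream in session.streams.items():
        fn = f"{name}_{site}.csv"
        write_stream(stream, outdir / fn)
        manifest["streams"][site] = fn
    ann_fn = f"{name}_annotations.csv"
    write_annotations(session.annotations, outdir / ann_fn)
    manifest["annotations"] = ann_fn

    if session.calibration is not None:
        cal: dict = {"standing": {}, "poses": []}
        for site, stream in session.calibration.standing.items():
            fn = f"{name}_cal_standing_{site}.csv"
            write_stream(stream, outdir / fn)
            cal["standing"][site] = fn
        for k, (angle, frags) in enumerate(session.calibration.flexion_poses):
            entry = {"angle_deg": float(angle), "streams": {}}
            for site, stream in frags.items():
                fn = f"{name}_cal_pose{k}_{site}.csv"
                write_stream(stream, outdir / fn)
                entry["streams"][site] = fn
            cal["poses"].append(entry)
        manifest["calibration"] = cal

    manifest_path = outdir / f"{name}_manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_session(manifest_path: str | Path) -> Session:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    streams = {
        site: read_stream(base / fn, site) for site, fn in manifest["streams"].items()
    }
    annotations = read_annotations(base / manifest["annotations"])
    calibration = None
    if "calibration" in manifest:
        cal = manifest["calibration"]
        standing = {s: read_stream(base / fn, s) for s, fn in cal["standing"].items()}
        poses = [
            (
                float(entry["angle_deg"]),
                {s: read_stream(base / fn, s) for s, fn in entry["streams"].items()},
            )
            for entry in cal["poses"]
        ]
        calibration = CalibrationSet(standing=standing, flexion_poses=poses)
    return Session(
        subject_id=str(manifest["subject_id"]),
        timepoint=manifest["timepoint"],
        side=manifest["side"],
        streams=streams,
        annotations=annotations,
        calibration=calibration,
    )


# ---------------------------------------------------------------------------
# reports


def round_half_away(value: float, ndigits: int) -> float:
    """Decimal rounding with ties away from zero (matches printed tables)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# report rounding mirrors the precision of the printed outcome tables:
# speeds and lengths 2 dp, times 2 dp, angles whole degrees, counts integers
_ROUNDING_RULES: list[tuple[tuple[str, ...], int]] = [
    (("speed", "step_length", "time", "duration", "sit_to_stand", "stand_to_sit"), 2),
    (("flexion", "excursion", "angle", "lean"), 0),
    (("cadence", "count", "steps"), 0),
    (("power", "amplitude"), 1),
    (("symmetry", "rho", "slope"), 2),
]


def decimals_for(column: str) -> int:
    for keys, nd in _ROUNDING_RULES:
        if any(k in column for k in keys):
            return nd
    return 3


def apply_report_rounding(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            nd = decimals_for(col)
            out[col] = out[col].map(lambda v: round_half_away(v, nd))
    return out


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a metrics/outcome report deterministically (CSV or JSON)."""
    path = Path(path)
    rounded = apply_report_rounding(report)
    if path.suffix == ".json":
        records = json.loads(rounded.to_json(orient="records"))
        with open(path, "w", newline="") as fh:
            json.dump(records, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        rounded.to_csv(path, index=False, lineterminator="\n")


def read_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path)
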