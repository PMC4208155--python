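"""Pre/post outcome statistics: deltas, score bands, correlations.

Combines per-session gait metrics with clinical knee scores (KSS, Knee
Society Score, 0-100 clinician-rated; OKS, Oxford Knee Score, 0-48
patient-reported; UCLA activity level 1-10) into per-patient pre/post
deltas, cohort means, banded score labels and rank correlations.  With
n = 6 patients the correlations are descriptive: Spearman's rho is
reported without p-values and without multiplicity correction.

A six-patient reference cohort (knee arthroplasty, measured the day
before and 12 months after surgery) ships with the package for worked
examples and regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

KSS_BANDS = ((60, "poor"), (70, "fair"), (80, "good"), (101, "excellent"))
OKS_BANDS = ((20, "poor"), (30, "fair"), (40, "good"), (49, "excellent"))

DEFAULT_CORRELATION_PAIRS = (
    ("running_speed", "oks"),
    ("walking_speed", "oks"),
    ("power_deceleration", "oks"),
    ("power_acceleration", "oks"),
    ("running_speed", "kss"),
)


def load_reference_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bundled reference cohort: (gait metrics, clinical scores) tables.

    Both are long tables with ``subject_id`` and ``timepoint`` (pre/post)
    columns; values carry the precision of the published summary tables.
    """
    base = resources.files("kneegait") / "data"
    metrics = pd.read_csv(base / "reference_cohort_metrics.csv", dtype={"subject_id": str})
    scores = pd.read_csv(base / "reference_cohort_scores.csv", dtype={"subject_id": str})
    return metrics, scores


def _band(value: float, bands) -> str:
    for upper, label in bands:
        if value < upper:
            return label
    raise ValidationError(f"score {value} out of range")


def kss_band(value: float) -> str:
    """KSS label: <60 poor, 60-69 fair, 70-79 good, 80-100 excellent."""
    if not 0 <= value <= 100:
        raise ValidationError("KSS outside 0-100")
    return _band(value, KSS_BANDS)


def oks_band(value: float) -> str:
    """OKS label: 0-19 poor, 20-29 fair, 30-39 good, 40-48 excellent."""
    if not 0 <= value <= 48:
        raise ValidationError("OKS outside 0-48")
    return _band(value, OKS_BANDS)


def band_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Append ``kss_band`` / ``oks_band`` label columns to a score table."""
    out = scores.copy()
    out["kss_band"] = out["kss"].map(kss_band)
    out["oks_band"] = out["oks"].map(oks_band)
    return out


def _split_timepoints(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    need = {"subject_id", "timepoint"}
    if not need <= set(table.columns):
        raise ValidationError("table needs subject_id and timepoint columns")
    pre = table[table["timepoint"] == "pre"].set_index("subject_id")
    post = table[table["timepoint"] == "post"].set_index("subject_id")
    return pre, post


def delta_table(table: pd.DataFrame, value_columns: list[str] | None = None) -> pd.DataFrame:
    """Per-patient pre/post/delta long table (delta = post - pre exactly).

    Only patients present at both timepoints contribute.
    """
    pre, post = _split_timepoints(table)
    common = pre.index.intersection(post.index)
    cols = value_columns or [
        c for c in table.columns
        if c not in ("subject_id", "timepoint")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    for sid in common:
        for c in cols:
            a, b = pre.loc[sid, c], post.loc[sid, c]
            rows.append(
                {"subject_id": sid, "metric": c, "pre": a, "post": b, "delta": b - a}
            )
    return pd.DataFrame(rows)


def cohort_means(deltas: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean pre/post/delta per metric over complete pre/post pairs."""
    g = deltas.dropna(subset=["pre", "post"]).groupby("metric", sort=False)
    out = g.agg(
        mean_pre=("pre", "mean"),
        mean_post=("post", "mean"),
        mean_delta=("delta", "mean"),
        n=("delta", "size"),
    ).reset_index()
    return out


def correlate(metric_values, score_values, method: str = "spearman") -> float:
    """Rank (Spearman, average ranks on ties) or Pearson correlation."""
    x = np.asarray(metric_values, float)
    y = np.asarray(score_values, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValidationError("need at least 4 paired values")
    if method == "spearman":
        return float(stats.spearmanr(x[ok], y[ok]).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x[ok], y[ok]).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


def correlate_metrics_scores(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    pairs=DEFAULT_CORRELATION_PAIRS,
    timepoint: str = "post",
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlations between gait metrics and clinical scores at a timepoint."""
    m = metrics[metrics["timepoint"] == timepoint].set_index("subject_id")
    s = scores[scores["timepoint"] == timepoint].set_index("subject_id")
    common = m.index.intersection(s.index)
    rows = []
    for metric, score in pairs:
        if metric not in m.columns or score not in s.columns:
            continue
        rho = correlate(m.loc[common, metric], s.loc[common, score], method)
        rows.append(
            {
                "metric": metric,
                "score": score,
                "timepoint": timepoint,
                "rho": rho,
                "n": len(common),
            }
        )
    return pd.DataFrame(rows)


def improvement_counts(table: pd.DataFrame, value_columns: list[str] | None = None) -> pd.DataFrame:
    """Patients improved (post > pre) per column of a long pre/post table."""
    deltas = delta_table(table, value_columns)
    if deltas.empty:
        return pd.DataFrame(columns=["metric", "n_improved", "n"])
    g = deltas.dropna(subset=["delta"]).groupby("metric", sort=False)
    return g.agg(
        n_improved=("delta", lambda d: int((d > 0).sum())), n=("delta", "size")
    ).reset_index()


@dataclass
class OutcomeReport:
    """Assembled pre/post outcome report for a cohort."""

    deltas: pd.DataFrame          # subject_id, metric, pre, post, delta
    cohort: pd.DataFrame          # metric, mean_pre, mean_post, mean_delta, n
    score_deltas: pd.DataFrame
    score_cohort: pd.DataFrame
    bands: pd.DataFrame           # banded score labels per subject x timepoint
    correlations: pd.DataFrame
    improvements: pd.DataFrame


def build_outcome_report(
    metrics: pd.DataFrame,
    scores: pd.DataFrame,
    correlation_pairs=DEFAULT_CORRELATION_PAIRS,
) -> OutcomeReport:
    """Full outcome report from long metric and score tables."""
    deltas = delta_table(metrics)
    score_deltas = delta_table(scores, ["kss", "oks"])
    return OutcomeReport(
        deltas=deltas,
        cohort=cohort_means(deltas),
        score_deltas=score_deltas,
        score_cohort=cohort_means(score_deltas),
        bands=band_scores(scores),
        correlations=correlate_metrics_scores(metrics, scores, correlation_pairs),
        improvements=pd.concat(
            [improvement_counts(metrics), improvement_counts(scores, ["kss", "oks"])],
            ignore_index=True,
        ),
    )
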