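"""Descriptive and inferential statistics over avoidance-event tables.

Works on event tables from the simulator, the synthetic generator, or
real-worm-style CSVs: collapse the four observed maneuver classes to the two
model classes, keep only the first event of each serial-avoidance run, bin
the reversal/curve choice ratio by encounter angle, summarize signed border
distances per maneuver, and run the variance (F) and mean (Student's t)
comparisons used to contrast assay conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "REVERSAL_LABELS",
    "CURVE_LABELS",
    "ChoiceSummary",
    "DistanceSummary",
    "collapse_maneuvers",
    "first_occurrence_filter",
    "drop_step_capped",
    "bin_choice_ratio",
    "distance_summary",
    "compare_variances",
    "compare_means",
]

REVERSAL_LABELS = {"long_reversal", "short_reversal", "reversal"}
CURVE_LABELS = {"gradual_curve", "deep_curve", "curve"}
_COLLAPSE = {
    "long_reversal": "reversal",
    "short_reversal": "reversal",
    "reversal": "reversal",
    "gradual_curve": "curve",
    "deep_curve": "curve",
    "curve": "curve",
}


@dataclass(frozen=True)
class ChoiceSummary:
    """Angle-binned reversal/curve choice ratio with Pearson correlation.

    ``reversal_ratio[i]`` is reversal/(reversal+curve) in the i-th angle bin;
    bins with fewer than ``min_count`` events are flagged and excluded from
    the correlation between bin midpoints and reversal ratio (two-sided
    p-value from the t transform).
    """

    bin_edges: np.ndarray
    reversal_count: np.ndarray
    curve_count: np.ndarray
    reversal_ratio: np.ndarray
    low_count_flag: np.ndarray
    pearson_r: Optional[float]
    p_value: Optional[float]
    min_count: int

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def n_events(self) -> int:
        return int(self.reversal_count.sum() + self.curve_count.sum())

    @property
    def reversal_fraction(self) -> float:
        return float(self.reversal_count.sum()) / self.n_events

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "reversal_count": self.reversal_count.tolist(),
            "curve_count": self.curve_count.tolist(),
            "reversal_ratio": [
                None if np.isnan(r) else float(r) for r in self.reversal_ratio
            ],
            "low_count_flag": self.low_count_flag.tolist(),
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "min_count": self.min_count,
        }


@dataclass(frozen=True)
class DistanceSummary:
    """Histogram and summary statistics of signed border distances (mm)."""

    maneuver: str
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: Optional[float]
    sd: Optional[float]
    quartiles: Optional[tuple]  # (q25, median, q75)

    def to_dict(self) -> dict:
        return {
            "maneuver": self.maneuver,
            "n": self.n,
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "quartiles": list(self.quartiles) if self.quartiles else None,
        }


def _require_columns(events: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")


def collapse_maneuvers(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse long/short reversal and gradual/deep curve to two classes.

    Already-collapsed labels pass through; the operation is idempotent.
    Rows labelled "none" (step-capped trials) pass through unchanged.
    Unknown labels raise, naming the offending row.
    """
    _require_columns(events, ["maneuver"])
    out = events.copy()
    labels = out["maneuver"].astype(str)
    bad = ~labels.isin(set(_COLLAPSE) | {"none"})
    if bad.any():
        idx = out.index[bad][0]
        raise ValueError(
            f"unknown maneuver label {labels.loc[idx]!r} at row {idx}"
        )
    out["maneuver"] = labels.map(lambda m: _COLLAPSE.get(m, m))
    return out


def first_occurrence_filter(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only the first event of each serial-avoidance run.

    A worm that fails to escape repeats avoidance maneuvers back to back;
    only the initial choice reflects the encounter geometry, so rows with
    sequence_index > 1 are dropped.
    """
    _require_columns(events, ["sequence_index"])
    return events.loc[events["sequence_index"] == 1].copy()


def drop_step_capped(events: pd.DataFrame) -> pd.DataFrame:
    """Remove step-capped trials (no terminal maneuver) if present."""
    if "terminated" in events.columns:
        return events.loc[events["terminated"] != "step_cap"].copy()
    return events.loc[events["maneuver"] != "none"].copy()


def bin_choice_ratio(
    events: pd.DataFrame,
    width: float = 10.0,
    min_count: int = 15,
) -> ChoiceSummary:
    """Bin the reversal/curve choice by encounter angle.

    Bins are half-open [lo, hi) over [0°, 90°], the last bin closed at 90°.
    Bins totalling fewer than ``min_count`` events are flagged and excluded
    from the Pearson correlation of reversal ratio against bin midpoint;
    fewer than 3 unflagged bins leaves the correlation undefined (with a
    warning).  Requires an already-collapsed two-class table.
    """
    _require_columns(events, ["maneuver", "angle_deg"])
    events = drop_step_capped(events)
    labels = set(events["maneuver"].unique())
    if not labels <= {"reversal", "curve"}:
        raise ValueError(
            f"collapse maneuvers to reversal/curve first (got {sorted(labels)})"
        )
    angles = events["angle_deg"].to_numpy(dtype=float)
    if ((angles < 0) | (angles > 90)).any():
        raise ValueError("encounter angles must lie in [0, 90] degrees")

    n_bins = int(round(90.0 / width))
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    idx = np.minimum((angles / width).astype(int), n_bins - 1)
    is_rev = (events["maneuver"] == "reversal").to_numpy()
    rev = np.bincount(idx[is_rev], minlength=n_bins)
    cur = np.bincount(idx[~is_rev], minlength=n_bins)
    total = rev + cur
    with np.errstate(invalid="ignore"):
        ratio = np.where(total > 0, rev / np.maximum(total, 1), np.nan)
        ratio[total == 0] = np.nan
    flag = total < min_count

    mid = (edges[:-1] + edges[1:]) / 2.0
    use = ~flag
    if use.sum() >= 3:
        r, p = sps.pearsonr(mid[use], ratio[use])
        r, p = float(r), float(p)
    else:
        warnings.warn(
            f"only {int(use.sum())} bins have >= {min_count} events; "
            "choice-ratio correlation is undefined",
            stacklevel=2,
        )
        r = p = None
    return ChoiceSummary(
        bin_edges=edges,
        reversal_count=rev,
        curve_count=cur,
        reversal_ratio=ratio,
        low_count_flag=flag,
        pearson_r=r,
        p_value=p,
        min_count=min_count,
    )


def distance_summary(
    events: pd.DataFrame, bin: float = 0.2
) -> Dict[str, DistanceSummary]:
    """Per-maneuver histogram and summary of signed border distances.

    Histogram bins are half-open [lo, hi) aligned to multiples of ``bin`` mm.
    Mean and SD (n−1 denominator) and quartiles accompany each histogram; a
    class with no events gets n = 0 and absent statistics, a single event an
    absent SD.
    """
    _require_columns(events, ["maneuver", "distance_mm"])
    events = drop_step_capped(events)
    out: Dict[str, DistanceSummary] = {}
    for maneuver in ("reversal", "curve"):
        d = events.loc[events["maneuver"] == maneuver, "distance_mm"].to_numpy(
            dtype=float
        )
        n = len(d)
        if n == 0:
            out[maneuver] = DistanceSummary(
                maneuver, 0, np.array([]), np.array([], dtype=int), None, None, None
            )
            continue
        lo = np.floor(d.min() / bin)
        hi = np.floor(d.max() / bin) + 1
        edges = np.arange(lo, hi + 1) * bin
        idx = (np.floor(d / bin) - lo).astype(int)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if n >= 2 else None
        q25, q50, q75 = (float(q) for q in np.percentile(d, [25, 50, 75]))
        out[maneuver] = DistanceSummary(
            maneuver, n, edges, counts, mean, sd, (q25, q50, q75)
        )
    return out


def compare_variances(a, b) -> tuple[float, float]:
    """Two-sided F test for equality of variances.

    F is the larger sample variance over the smaller; the p-value is twice
    the upper tail of F(n_larger−1, n_smaller−1), capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        F, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * float(sps.f.sf(F, dfn, dfd)))
    return float(F), p


def compare_means(a, b) -> tuple[float, float]:
    """Two-sample Student's t test (pooled variance), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
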