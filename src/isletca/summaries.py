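"""Per-condition event summaries, kernel density estimates, and two-sample tests.

Events are assigned to treatment conditions via a protocol timeline of
half-open intervals ``[start_s, end_s)``.  Distributions of halfwidth and
inter-event interval are summarized per condition by medians and by
Gaussian kernel density estimates with bandwidth ``factor x sample
standard deviation`` (factor 0.2 by default, the scalar ``bw_method``
convention).  Group differences use the Mann-Whitney U test (exact
enumeration for small samples, average-rank ties), Student's t-test, or
the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .events import iei_table

UNASSIGNED = "unassigned"


@dataclass
class ProtocolTimeline:
    """Ordered treatment intervals over recording time.

    ``intervals`` is a list of (start_s, end_s, label); intervals must be
    non-overlapping (gaps allowed) with unique labels.
    """

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        iv = sorted(self.intervals, key=lambda x: x[0])
        labels = [label for _, _, label in iv]
        if len(set(labels)) != len(labels):
            raise ValueError("interval labels must be unique")
        for start, end, _ in iv:
            if not start < end:
                raise ValueError("each interval must satisfy start < end")
        for (s0, e0, _), (s1, e1, _) in zip(iv[:-1], iv[1:]):
            if s1 < e0:
                raise ValueError("intervals must not overlap")
        self.intervals = iv

    def condition_at(self, t_s: float) -> str:
        for start, end, label in self.intervals:
            if start <= t_s < end:
                return label
        return UNASSIGNED

    @classmethod
    def from_json(cls, path) -> "ProtocolTimeline":
        with open(path) as fh:
            data = json.load(fh)
        return cls([(float(d["start_s"]), float(d["end_s"]), str(d["condition"])) for d in data])

    def to_json(self, path) -> None:
        data = [
            {"start_s": s, "end_s": e, "condition": c} for s, e, c in self.intervals
        ]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)


@dataclass
class KdeCurve:
    """A kernel density estimate evaluated on a grid and normalized on it."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth_factor: float
    n: int


@dataclass
class GroupComparison:
    """Result of a two-sample test."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int


def assign_condition(events: pd.DataFrame, timeline: ProtocolTimeline) -> pd.DataFrame:
    """Label each event by the half-open protocol interval containing its midtime.

    Events whose midtime falls in a gap or beyond the timeline receive the
    label ``"unassigned"``.
    """
    out = events.copy()
    out["condition"] = [timeline.condition_at(t) for t in out["midtime_s"]] if len(out) else []
    if not len(out):
        out["condition"] = pd.Series(dtype=str)
    return out


def kde(values, factor: float = 0.2, grid: np.ndarray | None = None) -> KdeCurve:
    """Gaussian kernel density estimate with bandwidth ``factor * std``.

    The scalar ``factor`` follows the usual ``bw_method`` convention: the
    kernel bandwidth is ``factor`` times the sample standard deviation.
    The curve is renormalized to unit trapezoidal integral on the grid.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("kde requires at least 2 observations")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("kde requires non-zero sample variance")
    k = stats.gaussian_kde(values, bw_method=factor)
    if grid is None:
        h = factor * sd
        grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, 512)
    grid = np.asarray(grid, dtype=float)
    density = k(grid)
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("grid does not cover the sample support")
    return KdeCurve(grid, density / area, factor, values.size)


def kde_difference(curve_a: KdeCurve, curve_b: KdeCurve) -> KdeCurve:
    """Pointwise difference of two KDEs on the same grid (integral ~ 0)."""
    if not np.array_equal(curve_a.grid, curve_b.grid):
        raise ValueError("KDE grids differ")
    return KdeCurve(
        curve_a.grid,
        curve_a.density - curve_b.density,
        curve_a.bandwidth_factor,
        curve_a.n + curve_b.n,
    )


def condition_medians(
    labeled_events: pd.DataFrame, iei_mode: str = "pooled"
) -> pd.DataFrame:
    """Median halfwidth and inter-event interval per condition.

    Halfwidths are pooled across ROIs within a condition.  Inter-event
    intervals are computed within each ROI; an interval is assigned to the
    condition of its earlier event and discarded when its two events lie in
    different conditions (avoids artifactual long intervals at solution
    changes).  ``iei_mode`` is ``"pooled"`` (default) or
    ``"per-roi-median"`` (median of per-ROI medians).
    """
    if iei_mode not in ("pooled", "per-roi-median"):
        raise ValueError(f"unknown iei_mode {iei_mode!r}")
    rows = []
    conditions = list(dict.fromkeys(labeled_events["condition"])) if len(labeled_events) else []
    ieis = _condition_ieis(labeled_events)
    for cond in conditions:
        sub = labeled_events[labeled_events["condition"] == cond]
        hw = sub["halfwidth_s"].to_numpy()
        cond_iei = ieis[ieis["condition"] == cond]
        if iei_mode == "pooled":
            iei_vals = cond_iei["interval_s"].to_numpy()
            med_iei = float(np.median(iei_vals)) if iei_vals.size else math.nan
        else:
            per_roi = cond_iei.groupby("roi_id")["interval_s"].median()
            med_iei = float(per_roi.median()) if len(per_roi) else math.nan
        rows.append(
            {
                "condition": cond,
                "median_halfwidth_s": float(np.median(hw)) if hw.size else math.nan,
                "median_iei_s": med_iei,
                "n_events": int(hw.size),
                "n_iei": int(len(cond_iei)),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "median_halfwidth_s", "median_iei_s", "n_events", "n_iei"])


def _condition_ieis(labeled_events: pd.DataFrame) -> pd.DataFrame:
    """Within-ROI IEIs labeled by the earlier event's condition; cross-condition pairs dropped."""
    if not len(labeled_events):
        return pd.DataFrame(columns=["roi_id", "interval_s", "condition"])
    rows = []
    for roi, grp in labeled_events.groupby("roi_id"):
        grp = grp.sort_values("midtime_s")
        mids = grp["midtime_s"].to_numpy()
        conds = grp["condition"].to_numpy()
        for i in range(len(mids) - 1):
            if conds[i] == conds[i + 1]:
                rows.append((roi, mids[i + 1] - mids[i], conds[i]))
    return pd.DataFrame(rows, columns=["roi_id", "interval_s", "condition"])


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact Mann-Whitney U by enumeration of all group labelings.

    Uses average ranks (tie-safe).  The two-sided p-value is the null
    probability that U deviates from its mean n_a*n_b/2 at least as much as
    observed.
    """
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu)
    total = 0
    hits = 0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def compare_groups(sample_a, sample_b, test: str = "mwu") -> GroupComparison:
    """Two-sample comparison.

    ``test`` is ``"mwu"`` (Mann-Whitney U; exact enumeration when the
    number of labelings is small, normal approximation otherwise),
    ``"t"`` (Student's t, equal variances), or ``"ks"``
    (two-sample Kolmogorov-Smirnov).  All tests are two-sided.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if test == "mwu":
        if a.size < 1 or b.size < 1:
            raise ValueError("mwu requires at least 1 observation per group")
        if math.comb(a.size + b.size, a.size) <= 20000:
            u, p = _mwu_exact(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        return GroupComparison("mwu", u, min(p, 1.0), a.size, b.size)
    if test == "t":
        if a.size < 3 or b.size < 3:
            raise ValueError("t-test requires at least 3 observations per group")
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), a.size, b.size)
    if test == "ks":
        if a.size < 1 or b.size < 1:
            raise ValueError("ks requires at least 1 observation per group")
        res = stats.ks_2samp(a, b)
        return GroupComparison("ks", float(res.statistic), float(res.pvalue), a.size, b.size)
    raise ValueError(f"unknown test {test!r}")


__all__ = [
    "ProtocolTimeline",
    "KdeCurve",
    "GroupComparison",
    "assign_condition",
    "kde",
    "kde_difference",
    "condition_medians",
    "compare_groups",
    "iei_table",
    "UNASSIGNED",
]
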