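"""Cell-size analytics: volumes, nuclei density, relative growth curves and
two-sample comparisons across nutrient conditions.

Cells of this organism are spherical, so microscopy reduces a cell to its
radius r and volume V = (4/3) pi r^3.  Size readouts compared across media
concentrations are: per-cell volume at fixed nuclear count, the
nuclei-to-volume ratio (a compactness measure), side-scatter summaries per
DNA-content bin, and time-lapse cell areas normalized to t = 0.  Group
comparisons use the two-sided Wilcoxon rank-sum (Mann-Whitney) test with
mid-rank tie handling: an exact permutation distribution (computed by
dynamic programming over the pooled ranks, valid with ties) for small
groups, and the tie-corrected normal approximation with continuity
correction otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError

__all__ = [
    "AreaSeries",
    "RankSumResult",
    "sphere_volume",
    "radius_from_volume",
    "radius_from_perimeter",
    "nuclei_volume_ratio",
    "relative_area",
    "compare_groups",
    "ssc_by_ploidy",
    "boxplot_stats",
]


def sphere_volume(radius):
    """Volume of a spherical cell, (4/3) pi r^3 (r in um -> um^3)."""
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise InvalidInputError("radius must be > 0")
    v = (4.0 / 3.0) * np.pi * r ** 3
    return float(v) if np.isscalar(radius) else v


def radius_from_volume(volume):
    """Inverse of :func:`sphere_volume`."""
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise InvalidInputError("volume must be > 0")
    r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(r) if np.isscalar(volume) else r


def radius_from_perimeter(perimeter):
    """Radius from a measured cell perimeter (circumference / 2 pi)."""
    p = np.asarray(perimeter, dtype=float)
    if np.any(p <= 0):
        raise InvalidInputError("perimeter must be > 0")
    r = p / (2.0 * np.pi)
    return float(r) if np.isscalar(perimeter) else r


def nuclei_volume_ratio(n_nuclei, volume):
    """Nuclei per cubic micrometer — how densely packed the coenocyte is."""
    n = np.asarray(n_nuclei, dtype=float)
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise InvalidInputError("volume must be > 0")
    r = n / v
    return float(r) if np.isscalar(volume) and np.isscalar(n_nuclei) else r


@dataclass(frozen=True)
class AreaSeries:
    """Time-lapse cell area normalized to the first frame."""

    cell_id: str
    times: np.ndarray
    areas: np.ndarray
    relative_areas: np.ndarray


def relative_area(
    times: Sequence[float], areas: Sequence[float], cell_id: str = ""
) -> AreaSeries:
    """Normalize a time-lapse area series to its t = 0 value.

    The first relative area is exactly 1; normalization makes growth curves
    comparable across cells of different starting size.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    if t.shape != a.shape or t.size == 0:
        raise InvalidInputError("times and areas must be equal-length, non-empty")
    if not np.isclose(t[0], 0.0):
        raise InvalidInputError("series must start at t = 0")
    if np.any(a <= 0):
        raise InvalidInputError("areas must be > 0")
    rel = a / a[0]
    rel[0] = 1.0
    return AreaSeries(cell_id=cell_id, times=t, areas=a, relative_areas=rel)


@dataclass(frozen=True)
class RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two samples.

    ``direction`` is +1 when sample a tends larger than sample b (its rank
    sum exceeds the null expectation), -1 when smaller, 0 when equal.
    ``method`` records which path produced the p-value.
    """

    statistic: float
    p_value: float
    direction: int
    n_a: int
    n_b: int
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic_rank_sum_a": self.statistic,
            "p_value": self.p_value,
            "direction": self.direction,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "method": self.method,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_ranksum_pvalue(ranks_a: np.ndarray, all_ranks: np.ndarray) -> float:
    """Exact two-sided p-value of the rank-sum statistic under the
    permutation null, valid in the presence of ties.

    Mid-ranks are multiples of 1/2, so doubling makes them integers; a
    dynamic program counts, for each subset size, how many subsets of the
    pooled ranks achieve each possible sum.  Two-sided p is
    2 * min(P(W <= w), P(W >= w)) capped at 1 — the convention that
    reproduces naive enumeration over all C(n, n_a) assignments.
    """
    doubled = np.round(2 * all_ranks).astype(np.int64)
    w_obs = int(np.round(2 * ranks_a.sum()))
    n, k = doubled.size, ranks_a.size
    total = int(doubled.sum())
    # counts[j, s] = number of j-subsets with doubled-rank sum s
    counts = np.zeros((k + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled:
        for j in range(min(k, n) - 1, -1, -1):
            counts[j + 1, r:] += counts[j, : total + 1 - r]
    dist = counts[k]
    n_total = dist.sum()
    p_le = dist[: w_obs + 1].sum() / n_total
    p_ge = dist[w_obs:].sum() / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def compare_groups(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_threshold: int = 20,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Groups with at most ``exact_threshold`` observations each are compared
    against the exact permutation distribution of the rank sum (tie-aware);
    larger groups use the tie-corrected normal approximation with continuity
    correction.  The reported statistic is the rank sum of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    ranks_a = ranks[: a.size]
    w = float(ranks_a.sum())
    expected = a.size * (pooled.size + 1) / 2.0
    direction = int(np.sign(w - expected))
    if max(a.size, b.size) <= exact_threshold:
        p = _exact_ranksum_pvalue(ranks_a, ranks)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
        method = "normal-approximation"
    return RankSumResult(
        statistic=w, p_value=p, direction=direction,
        n_a=int(a.size), n_b=int(b.size), method=method,
    )


def boxplot_stats(values: Sequence[float]) -> dict:
    """Tukey boxplot summary: median, quartiles (linear interpolation),
    1.5-IQR whiskers clipped to the data, and outlier count."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(v.size - inside.size),
    }


def ssc_by_ploidy(
    binned_events: pd.DataFrame,
    schedule: Mapping[float, float],
    min_events: int = 250,
) -> pd.DataFrame:
    """Side-scatter summaries per DNA-content bin at scheduled time points.

    Each ploidy bin is summarized only from the single time point where that
    population is most abundant (the ``schedule``), e.g. 16C and 32C from
    36 h, 64C and 128C from 48 h, newborn 2C from 60 h.  Bins with fewer than
    ``min_events`` events at their scheduled time are reported with
    ``missing=True`` rather than pooled across times.  Groups by
    ``condition`` when that column is present.
    """
    if not schedule:
        raise InvalidInputError("empty schedule")
    conditions = (
        sorted(binned_events["condition"].unique())
        if "condition" in binned_events.columns
        else [None]
    )
    rows = []
    for cond in conditions:
        sub = (
            binned_events
            if cond is None
            else binned_events[binned_events["condition"] == cond]
        )
        for ploidy, t in sorted(schedule.items()):
            sel = sub[
                (~sub["debris"])
                & (sub["ploidy_c"] == ploidy)
                & np.isclose(sub["time_h"], t)
            ]
            row = {"condition": cond, "ploidy_c": ploidy, "time_h": t,
                   "n": int(len(sel))}
            if len(sel) < min_events:
                row.update({"missing": True, "median": math.nan,
                            "q1": math.nan, "q3": math.nan})
            else:
                q1, med, q3 = np.percentile(sel["ssc"], [25, 50, 75])
                row.update({"missing": False, "median": float(med),
                            "q1": float(q1), "q3": float(q3)})
            rows.append(row)
    return pd.DataFrame(rows)
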