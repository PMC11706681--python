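"""Two-sample comparisons between conditions: Kolmogorov-Smirnov testing,
kernel density estimation, and the per-bin comparison harness.

The central tool is the non-parametric two-sample Kolmogorov-Smirnov test.
Count data are heavily tied, so the D statistic is the exact supremum of the
ECDF difference evaluated over the union of sample points; the p-value comes
from the asymptotic Kolmogorov distribution with effective sample size
``n1*n2/(n1+n2)`` (an exact option is available for small samples).  Reports
flag samples whose tie fraction exceeds 50%, where the asymptotic p-value is
approximate, and no multiple-testing correction is applied — the number of
comparisons is reported so users can apply their own.

`run_comparisons` reproduces the condition-by-window analysis design:
intact vs regenerating, for the pooled recording and for each temporal bin
(0-6, 6-24, 24-72, >72 h), across three metrics — events per frame, burst
sizes, and pairwise cluster-centre distances.  Cells with fewer than three
values on either side are marked insufficient rather than tested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special as _special
from scipy import stats as _stats

from .events_io import TIME_BINS, EventTable, TimeBin, time_bin_of
from .spatial import ClusterParams, cluster_table, pairwise_centre_distances
from .temporal import burst_threshold, counts_per_frame, detect_bursts, frame_series_by_root

__all__ = [
    "ComparisonCell",
    "ComparisonReport",
    "KSResult",
    "METRICS",
    "gaussian_kde",
    "ks_two_sample",
    "run_comparisons",
    "tie_fraction",
    "verdict",
]

METRICS = ("events_per_frame", "burst_sizes", "centre_distances")


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov statistic and p-value."""

    d_stat: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(a: Sequence[float], b: Sequence[float], method: str = "asymptotic") -> KSResult:
    """Two-sample K-S test with tie-correct ECDF supremum.

    ``method='asymptotic'`` (default) evaluates the Kolmogorov distribution
    at ``sqrt(n1*n2/(n1+n2)) * D``; ``method='exact'`` uses the exact
    small-sample distribution (recommended only for ``n1*n2 <= 10_000``).
    """
    xa = np.sort(np.asarray(a, dtype=float))
    xb = np.sort(np.asarray(b, dtype=float))
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.union1d(xa, xb)
    fa = np.searchsorted(xa, grid, side="right") / xa.size
    fb = np.searchsorted(xb, grid, side="right") / xb.size
    d = float(np.max(np.abs(fa - fb)))
    if method == "exact":
        p = float(_stats.ks_2samp(xa, xb, method="exact").pvalue)
    elif method == "asymptotic":
        ne = xa.size * xb.size / (xa.size + xb.size)
        p = float(np.clip(_special.kolmogorov(math.sqrt(ne) * d), 0.0, 1.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(d, p, int(xa.size), int(xb.size))


def tie_fraction(sample: Sequence[float]) -> float:
    """Fraction of values that duplicate an earlier value."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        return 0.0
    return 1.0 - np.unique(x).size / x.size


def gaussian_kde(
    sample: Sequence[float], bw_method: str | float = "scott", grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate on a regular grid.

    Scott's-rule bandwidth by default; the grid spans the sample range
    extended by three bandwidths.  Returns ``(grid, density)``.  Degenerate
    (zero-variance) samples raise — use a histogram for those.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("kernel density estimation needs at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: use a histogram instead of a KDE")
    kde = _stats.gaussian_kde(x, bw_method=bw_method)
    h = float(kde.factor * x.std(ddof=1))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return grid, kde(grid)


def verdict(p_value: float) -> str:
    """Significance wording: <0.001 highly, <0.01 significant, <0.05 marginal."""
    if p_value < 0.001:
        return "highly significant"
    if p_value < 0.01:
        return "significant"
    if p_value < 0.05:
        return "marginally significant"
    return "not significant"


@dataclass
class ComparisonCell:
    """One window x metric comparison between the two conditions."""

    window: str
    metric: str
    status: str  # "ok" | "insufficient-data"
    result: KSResult | None = None
    tie_flag: bool = False

    @property
    def verdict(self) -> str:
        if self.status != "ok":
            return "insufficient data"
        return verdict(self.result.p_value)

    def to_jsonable(self) -> dict:
        out: dict = {"window": self.window, "metric": self.metric, "status": self.status,
                     "verdict": self.verdict, "tie_flag": self.tie_flag}
        if self.result is not None:
            out.update(
                d_stat=self.result.d_stat, p_value=self.result.p_value,
                n1=self.result.n1, n2=self.result.n2,
            )
        return out


@dataclass
class ComparisonReport:
    """All window x metric K-S comparisons plus the conventions used."""

    condition_a: str
    condition_b: str
    cells: list[ComparisonCell]
    conventions: dict = field(default_factory=dict)

    @property
    def n_comparisons(self) -> int:
        return sum(1 for c in self.cells if c.status == "ok")

    def get(self, window: str, metric: str) -> ComparisonCell:
        for c in self.cells:
            if c.window == window and c.metric == metric:
                return c
        raise KeyError((window, metric))

    def to_jsonable(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "n_comparisons": self.n_comparisons,
            "conventions": self.conventions,
            "cells": [c.to_jsonable() for c in self.cells],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_jsonable(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"Comparison: {self.condition_a} vs {self.condition_b} "
            f"({self.n_comparisons} tests, no multiple-testing correction)",
            f"{'window':<8} {'metric':<18} {'D':>7} {'p':>10} {'n1':>5} {'n2':>5}  verdict",
        ]
        for c in self.cells:
            if c.status == "ok":
                r = c.result
                tie = " (ties>50%)" if c.tie_flag else ""
                lines.append(
                    f"{c.window:<8} {c.metric:<18} {r.d_stat:7.3f} {r.p_value:10.3g} "
                    f"{r.n1:5d} {r.n2:5d}  {c.verdict}{tie}"
                )
            else:
                lines.append(f"{c.window:<8} {c.metric:<18} {'-':>7} {'-':>10} {'-':>5} {'-':>5}  insufficient data")
        return "\n".join(lines)


def _window_mask(times_h: np.ndarray, window: str) -> np.ndarray:
    if window == "all":
        return np.ones(len(times_h), dtype=bool)
    b = next(tb for tb in TIME_BINS if tb.label == window)
    return (times_h >= b.lower_h) & (times_h < b.upper_h)


def run_comparisons(
    table: EventTable,
    cluster_params: ClusterParams | None = ClusterParams(),
    metrics: Sequence[str] = METRICS,
    pooling: str = "per-condition",
    min_n: int = 3,
) -> ComparisonReport:
    """Intact-vs-regenerating K-S comparisons per temporal bin and metric.

    Per condition, per-frame counts are pooled across roots (the burst
    threshold is computed per condition by default); burst sizes and
    pairwise cluster-centre distances are pooled across roots and frames
    within each window.  Pass ``cluster_params=None`` or drop
    ``'centre_distances'`` from ``metrics`` to skip the spatial stage.
    """
    conds = table.conditions
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, found {conds}")
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    if pooling not in ("per-condition", "per-root"):
        raise ValueError("pooling must be 'per-condition' or 'per-root'")

    dt = table.delta_t_h
    frame_times = np.arange(table.n_frames) * dt

    # per condition: pooled counts with times, burst (time, size), distance (time, value)
    counts_by_cond: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    bursts_by_cond: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    dists_by_cond: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    thresholds: dict[str, float] = {}

    for cond in conds:
        series = frame_series_by_root(table, cond)
        times = np.concatenate([frame_times for _ in series]) if series else np.empty(0)
        counts = np.concatenate([s.counts for s in series]) if series else np.empty(0)
        counts_by_cond[cond] = (times, counts)

        if "burst_sizes" in metrics:
            thr_cond = burst_threshold(series)
            bt, bs = [], []
            for s in series:
                thr = thr_cond if pooling == "per-condition" else burst_threshold(s)
                burst = detect_bursts(s, thr)
                bt.extend(f * dt for f in burst.frames)
                bs.extend(burst.sizes)
            thresholds[cond] = thr_cond
            bursts_by_cond[cond] = (np.asarray(bt, dtype=float), np.asarray(bs, dtype=float))

    if "centre_distances" in metrics and cluster_params is not None:
        _, summaries = cluster_table(table, cluster_params)
        cond_of = {r: table.condition_of(r) for r in table.root_ids}
        acc: dict[str, tuple[list, list]] = {c: ([], []) for c in conds}
        for s in summaries:
            d = pairwise_centre_distances(s)
            if d.size:
                t_list, d_list = acc[cond_of[s.root_id]]
                t_list.extend([s.frame_index * dt] * d.size)
                d_list.extend(d)
        for c in conds:
            t_list, d_list = acc[c]
            dists_by_cond[c] = (np.asarray(t_list, dtype=float), np.asarray(d_list, dtype=float))

    samples = {
        "events_per_frame": counts_by_cond,
        "burst_sizes": bursts_by_cond,
        "centre_distances": dists_by_cond,
    }
    windows = ["all"] + [b.label for b in TIME_BINS]
    cells: list[ComparisonCell] = []
    ca, cb = conds
    for metric in metrics:
        if metric == "centre_distances" and not dists_by_cond:
            for w in windows:
                cells.append(ComparisonCell(w, metric, "insufficient-data"))
            continue
        for w in windows:
            pair = []
            for cond in (ca, cb):
                times, values = samples[metric][cond]
                pair.append(values[_window_mask(times, w)])
            if min(len(pair[0]), len(pair[1])) < min_n:
                cells.append(ComparisonCell(w, metric, "insufficient-data"))
            else:
                res = ks_two_sample(pair[0], pair[1])
                flag = max(tie_fraction(pair[0]), tie_fraction(pair[1])) > 0.5
                cells.append(ComparisonCell(w, metric, "ok", res, flag))

    conventions = {
        "pooling": pooling,
        "p_value": "asymptotic Kolmogorov, effective n = n1*n2/(n1+n2)",
        "burst_thresholds": thresholds,
        "min_n": min_n,
    }
    if cluster_params is not None and "centre_distances" in metrics:
        conventions["epsilon_um"] = cluster_params.epsilon_um
        conventions["min_samples"] = cluster_params.min_samples
    return ComparisonReport(ca, cb, cells, conventions)
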