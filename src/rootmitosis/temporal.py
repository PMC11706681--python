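"""Temporal statistics of per-frame event counts.

The time series of divisions per frame is intermittent: a noisy baseline
punctuated by isolated high-activity frames.  This module quantifies that
pattern three ways:

* **Bursts** — a burst is a single frame whose count is at least one
  standard deviation above the mean of the reference series; its size is
  that frame's count.  The threshold is computed by pooling the per-frame
  counts of all roots of a condition by default (one threshold per
  condition), using the sample standard deviation (n-1 denominator).
* **Poisson null** — if divisions were independent, burst sizes would look
  like (the tail of) a Poisson count distribution.  `mode_matched_poisson`
  builds the classical overlay whose mode equals the observed one
  (lambda = mode + 0.5, the midpoint of the interval [mode, mode+1) of
  rates sharing that mode); `fit_poisson_tail` fits a Poisson by maximum
  likelihood to the burst sample *restricted to the burst support*, which
  is the statistically well-posed version of the same question (burst sizes
  are by construction a >=-threshold tail, so an untruncated comparison
  rejects even for perfectly Poissonian counts).  `compare_to_poisson`
  measures the discrete one-sample Kolmogorov-Smirnov divergence against
  either null.
* **Periodogram** — a plain FFT power spectral density of the mean-removed,
  unwindowed series on the native Fourier grid, reported against period in
  hours, with local-maxima peak extraction and a Bonferroni-corrected
  white-noise significance threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import special as _special
from scipy import stats as _stats
from scipy.optimize import minimize_scalar

from .events_io import EventTable

__all__ = [
    "BurstSet",
    "FrameSeries",
    "PeriodogramResult",
    "PoissonComparison",
    "PoissonNull",
    "average_periodograms",
    "burst_threshold",
    "compare_to_poisson",
    "counts_per_frame",
    "detect_bursts",
    "fit_poisson_tail",
    "frame_series_by_root",
    "mode_matched_poisson",
    "periodogram",
    "top_periods",
    "white_noise_threshold",
]


@dataclass
class FrameSeries:
    """Ordered per-frame event counts for one root."""

    root_id: str
    condition: str
    counts: np.ndarray
    delta_t_h: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValueError("counts must be a non-empty 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.delta_t_h > 0:
            raise ValueError("delta_t_h must be positive")

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.delta_t_h

    def __len__(self) -> int:
        return len(self.counts)


def counts_per_frame(table: EventTable, root_id: str) -> FrameSeries:
    """Events per frame for one root, zero-filled over the full frame grid."""
    sub = table.for_root(root_id)
    counts = np.bincount(sub["frame_index"].to_numpy(), minlength=table.n_frames)
    return FrameSeries(root_id, table.condition_of(root_id), counts.astype(np.int64), table.delta_t_h)


def frame_series_by_root(table: EventTable, condition: str | None = None) -> list[FrameSeries]:
    """Per-root series for every root (optionally restricted to a condition)."""
    roots = table.root_ids if condition is None else [
        r for r in table.root_ids if table.condition_of(r) == condition
    ]
    return [counts_per_frame(table, r) for r in roots]


def burst_threshold(series_group: FrameSeries | Iterable[FrameSeries], ddof: int = 1) -> float:
    """Mean + 1 standard deviation of the pooled per-frame counts.

    ``series_group`` may be a single series or an iterable (e.g. all roots of
    one condition, the default pooling scope of the pipeline).  ``ddof=1``
    selects the sample standard deviation.
    """
    if isinstance(series_group, FrameSeries):
        series_group = [series_group]
    pooled = np.concatenate([np.asarray(s.counts, dtype=float) for s in series_group])
    if pooled.size == 0:
        raise ValueError("burst_threshold requires at least one frame")
    sd = 0.0 if pooled.size <= ddof else float(np.std(pooled, ddof=ddof))
    return float(np.mean(pooled)) + sd


@dataclass
class BurstSet:
    """Frames whose count reaches the burst threshold, with their sizes."""

    threshold: float
    bursts: list[tuple[int, int]]  # (frame_index, size), sorted by frame

    @property
    def frames(self) -> np.ndarray:
        return np.array([f for f, _ in self.bursts], dtype=np.int64)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s for _, s in self.bursts], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.bursts)


def detect_bursts(series: FrameSeries, threshold: float) -> BurstSet:
    """All frames with ``count >= threshold`` (and at least one event)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    counts = np.asarray(series.counts)
    mask = (counts >= threshold) & (counts > 0)
    bursts = [(int(f), int(counts[f])) for f in np.flatnonzero(mask)]
    return BurstSet(float(threshold), bursts)


@dataclass(frozen=True)
class PoissonNull:
    """A Poisson reference distribution with an explicit mode."""

    lam: float
    mode: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if math.floor(self.lam) != self.mode and self.lam != self.mode:
            raise ValueError(f"mode {self.mode} inconsistent with lam {self.lam}")

    def pmf(self, k) -> np.ndarray:
        return _stats.poisson.pmf(k, self.lam)

    def cdf(self, k) -> np.ndarray:
        return _stats.poisson.cdf(k, self.lam)


def mode_matched_poisson(mode: int) -> PoissonNull:
    """Poisson null whose most probable value equals ``mode``.

    Any rate in [mode, mode+1) has that mode; the midpoint mode + 0.5 is
    used, so e.g. mode 11 -> lambda 11.5.
    """
    mode = int(mode)
    if mode < 0:
        raise ValueError("mode must be >= 0")
    return PoissonNull(lam=mode + 0.5, mode=mode)


def fit_poisson_tail(sizes: Sequence[int], min_size: int) -> PoissonNull:
    """Maximum-likelihood Poisson fit to a sample truncated to ``>= min_size``.

    Answers "could these burst sizes be the tail of a single Poisson count
    distribution?" — the appropriate null when the sample was selected by a
    threshold.
    """
    x = np.asarray(sizes, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x < min_size):
        raise ValueError("sample contains values below min_size")

    def nll(lam: float) -> float:
        logpmf = _stats.poisson.logpmf(x, lam)
        log_tail = np.log1p(-_stats.poisson.cdf(min_size - 1, lam))
        return float(-(logpmf.sum() - x.size * log_tail))

    hi = max(float(x.mean()), 1.0)
    res = minimize_scalar(nll, bounds=(1e-9, hi), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(res.x)
    return PoissonNull(lam=lam, mode=math.floor(lam))


@dataclass
class PoissonComparison:
    """Divergence of a burst-size sample from a Poisson null."""

    d_stat: float
    p_value: float
    n: int
    sizes: np.ndarray           # unique observed sizes
    empirical_freq: np.ndarray  # relative frequency of each size
    model_pmf: np.ndarray       # null pmf at each size (truncated if min_size)
    min_size: int | None = None


def compare_to_poisson(
    burst_sizes: Sequence[int], null: PoissonNull, min_size: int | None = None
) -> PoissonComparison:
    """Discrete one-sample Kolmogorov-Smirnov comparison against a Poisson.

    If ``min_size`` is given, the null is renormalised to the support
    ``{min_size, min_size+1, ...}`` — use the burst threshold here when the
    sample is a burst-size sample, so the comparison is not dominated by the
    thresholding itself.  The p-value uses the asymptotic Kolmogorov
    distribution and is conservative for discrete data.
    """
    x = np.asarray(burst_sizes, dtype=np.int64)
    if x.size == 0:
        raise ValueError("empty sample")
    uniq, counts = np.unique(x, return_counts=True)
    n = x.size
    ecdf = np.cumsum(counts) / n
    ecdf_prev = np.concatenate([[0.0], ecdf[:-1]])

    F = np.asarray(null.cdf(uniq), dtype=float)
    F_prev = np.asarray(null.cdf(uniq - 1), dtype=float)
    if min_size is not None:
        base = float(null.cdf(min_size - 1))
        tail = 1.0 - base
        if tail <= 0:
            raise ValueError("null has no mass on the truncated support")
        F = np.clip((F - base) / tail, 0.0, 1.0)
        F_prev = np.clip((F_prev - base) / tail, 0.0, 1.0)
    d = float(np.max(np.maximum(np.abs(ecdf - F), np.abs(ecdf_prev - F_prev))))
    p = float(np.clip(_special.kolmogorov(math.sqrt(n) * d), 0.0, 1.0))

    pmf = np.asarray(null.pmf(uniq), dtype=float)
    if min_size is not None:
        pmf = pmf / tail
    return PoissonComparison(d, p, n, uniq, counts / n, pmf, min_size)


@dataclass
class PeriodogramResult:
    """One-sided power spectral density against period in hours.

    ``period_h`` decreases along the array (frequency increases); the DC
    component is excluded.  ``peaks`` are local PSD maxima sorted by
    descending power.
    """

    period_h: np.ndarray
    psd: np.ndarray
    peaks: list[tuple[float, float]]
    delta_t_h: float
    n: int  # length of the analysed series

    @property
    def freq_per_h(self) -> np.ndarray:
        return 1.0 / self.period_h

    @property
    def df(self) -> float:
        """Frequency-bin width (1/h)."""
        return 1.0 / (self.n * self.delta_t_h)


def _find_peaks(period: np.ndarray, psd: np.ndarray) -> list[tuple[float, float]]:
    n = len(psd)
    idx: list[int] = []
    for i in range(n):
        left_ok = i == 0 or psd[i] > psd[i - 1]
        right_ok = i == n - 1 or psd[i] >= psd[i + 1]
        if left_ok and right_ok and psd[i] > 0:
            idx.append(i)
    idx.sort(key=lambda i: (-psd[i], period[i]))
    return [(float(period[i]), float(psd[i])) for i in idx]


def periodogram(series: FrameSeries) -> PeriodogramResult:
    """FFT periodogram of the mean-removed counts (no window, native grid).

    The one-sided density normalisation satisfies Parseval's identity:
    ``sum(psd) * df`` equals the variance of the mean-removed series.
    """
    x = np.asarray(series.counts, dtype=float)
    if len(x) < 4:
        raise ValueError("periodogram requires at least 4 frames")
    fs = 1.0 / series.delta_t_h
    freqs, psd = _signal.periodogram(
        x, fs=fs, window="boxcar", detrend="constant", scaling="density"
    )
    freqs, psd = freqs[1:], psd[1:]  # drop DC
    period = 1.0 / freqs
    return PeriodogramResult(period, psd, _find_peaks(period, psd), series.delta_t_h, len(x))


def top_periods(pg: PeriodogramResult, k: int) -> list[float]:
    """Periods (hours) of the ``k`` highest-power peaks (fewer if fewer exist)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [p for p, _ in pg.peaks[:k]]


def white_noise_threshold(pg: PeriodogramResult, alpha: float = 0.05) -> float:
    """Bonferroni-corrected PSD level a white-noise series stays below.

    Periodogram ordinates of white noise are ~exponential with mean equal to
    the average PSD level; the maximum of M ordinates exceeds
    ``mean * ln(M/alpha)`` with probability at most ``alpha``.
    """
    m = len(pg.psd)
    return float(np.mean(pg.psd) * math.log(m / alpha))


def average_periodograms(pgs: Sequence[PeriodogramResult]) -> PeriodogramResult:
    """Average PSDs of several roots computed on the same frequency grid."""
    if not pgs:
        raise ValueError("need at least one periodogram")
    ref = pgs[0]
    for pg in pgs[1:]:
        if pg.n != ref.n or pg.delta_t_h != ref.delta_t_h:
            raise ValueError("periodograms must share the same frequency grid")
    psd = np.mean([pg.psd for pg in pgs], axis=0)
    return PeriodogramResult(
        ref.period_h.copy(), psd, _find_peaks(ref.period_h, psd), ref.delta_t_h, ref.n
    )
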