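"""Synthetic spatiotemporal event tables with the statistical structure the
analysis assumes.

Temporal model: per-frame event counts are Poisson with mean

    lambda(t) = lambda_base * (1 + mod_amplitude * cos(2*pi * t*dt / period_h))

optionally punctuated by burst episodes: with probability ``burst_rate`` per
frame the count receives an extra Poisson(``burst_size_mean``) increment.
Both burst parameters may switch to "late" values at ``burst_onset_h``, which
lets a regeneration-like effect appear only after a chosen time while the
pre-onset process stays identical to a control.

Spatial model: a Thomas (Neyman-Scott) cluster process per frame.  Parent
centres are uniform in an axis-aligned box; each parent receives
max(1, Poisson(``events_per_cluster_mean``)) offspring until the frame's
event budget is consumed, and offspring are displaced isotropically by a
Gaussian of scale ``cluster_sigma_um`` and clipped to the box.  Temporal and
spatial processes are independent.

Reproducibility: one global seed expands into per-root substreams keyed by
(seed, condition ordinal, root ordinal), so adding roots or conditions never
perturbs previously generated ones, and identical seeds give bit-identical
tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .events_io import EventTable

__all__ = [
    "PositionTruth",
    "SynthConfig",
    "TableTruth",
    "intact_defaults",
    "regenerating_defaults",
    "simulate_counts",
    "simulate_counts_with_truth",
    "simulate_positions",
    "simulate_positions_with_truth",
    "simulate_table",
    "simulate_table_with_truth",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters for one condition.

    Defaults emulate an intact root imaged every 15 minutes for 7 days:
    a baseline of ~4 events/frame (count mode 3-4), occasional bursts
    (5% of frames, ~10 extra events), a 24-h modulation from the entrained
    light cycle, and spatial clusters of 2-4 events (mean 3) with ~4 um
    within-cluster spread in a 120 um meristem-scale box.
    """

    n_frames: int = 672
    delta_t_h: float = 0.25
    lambda_base: float = 4.0
    burst_rate: float = 0.05
    burst_size_mean: float = 10.0
    burst_rate_late: float | None = None
    burst_size_mean_late: float | None = None
    burst_onset_h: float = 24.0
    period_h: float = 24.0
    mod_amplitude: float = 0.3
    domain_um: tuple[float, float, float] = (120.0, 120.0, 120.0)
    cluster_sigma_um: float = 4.0
    events_per_cluster_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.delta_t_h > 0:
            raise ValueError("delta_t_h must be positive")
        if self.lambda_base < 0:
            raise ValueError("lambda_base must be >= 0")
        for name in ("burst_rate", "burst_rate_late"):
            r = getattr(self, name)
            if r is not None and not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if not 0.0 <= self.mod_amplitude <= 1.0:
            raise ValueError("mod_amplitude must lie in [0, 1]")
        if self.mod_amplitude > 0 and self.period_h <= 0:
            raise ValueError("period_h must be positive when mod_amplitude > 0")
        if not self.cluster_sigma_um > 0:
            raise ValueError("cluster_sigma_um must be positive")
        if self.events_per_cluster_mean < 0:
            raise ValueError("events_per_cluster_mean must be >= 0")
        if any(d <= 0 for d in self.domain_um):
            raise ValueError("domain_um extents must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def replace(self, **changes) -> "SynthConfig":
        return dataclasses.replace(self, **changes)


def intact_defaults(seed: int = 0) -> SynthConfig:
    """Study conditions for an unperturbed root (see class docstring)."""
    return SynthConfig(seed=seed)


def regenerating_defaults(seed: int = 0) -> SynthConfig:
    """Study conditions for a regenerating root.

    Identical to the intact process before 24 h; afterwards bursts become
    more frequent (20% of frames) and larger (mean 14 extra events), and the
    modulation is a 16-h component of larger amplitude — the qualitative
    signature of the regeneration dynamics this package quantifies.
    """
    return SynthConfig(
        seed=seed,
        burst_rate_late=0.2,
        burst_size_mean_late=14.0,
        burst_onset_h=24.0,
        period_h=16.0,
        mod_amplitude=0.5,
    )


def _counts_rng(config: SynthConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, 0, 0)))


def _positions_rng(config: SynthConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, 0, 1)))


def _simulate_counts(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    t_h = np.arange(config.n_frames) * config.delta_t_h
    lam = np.full(config.n_frames, float(config.lambda_base))
    if config.mod_amplitude > 0:
        lam *= 1.0 + config.mod_amplitude * np.cos(2.0 * np.pi * t_h / config.period_h)
    counts = rng.poisson(lam)

    rate_late = config.burst_rate if config.burst_rate_late is None else config.burst_rate_late
    size_late = (
        config.burst_size_mean if config.burst_size_mean_late is None else config.burst_size_mean_late
    )
    late = t_h >= config.burst_onset_h
    rate = np.where(late, rate_late, config.burst_rate)
    size_mean = np.where(late, size_late, config.burst_size_mean)
    burst_mask = rng.random(config.n_frames) < rate
    counts[burst_mask] += rng.poisson(size_mean[burst_mask])
    return counts.astype(np.int64), np.flatnonzero(burst_mask)


def simulate_counts(config: SynthConfig) -> np.ndarray:
    """Per-frame event counts for one root (length ``config.n_frames``)."""
    return _simulate_counts(config, _counts_rng(config))[0]


def simulate_counts_with_truth(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Counts plus the frame indices where a burst increment was injected."""
    return _simulate_counts(config, _counts_rng(config))


@dataclass(frozen=True)
class PositionTruth:
    """Generator bookkeeping for one spatial draw."""

    parent_centres: np.ndarray  # (m, 3)
    parent_index: np.ndarray    # (n,) offspring -> parent
    offspring_counts: np.ndarray  # (m,)

    @property
    def n_parents(self) -> int:
        return len(self.parent_centres)

    def n_occupied_parents(self, min_offspring: int = 1) -> int:
        """Parents with at least ``min_offspring`` events (identifiable clusters)."""
        return int(np.sum(self.offspring_counts >= min_offspring))


def _simulate_positions(
    n_events: int, config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, PositionTruth]:
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    box = np.asarray(config.domain_um, dtype=float)
    parents: list[np.ndarray] = []
    counts: list[int] = []
    chunks: list[np.ndarray] = []
    remaining = n_events
    while remaining > 0:
        centre = rng.uniform(0.0, box)
        k = max(1, int(rng.poisson(config.events_per_cluster_mean)))
        k = min(k, remaining)
        offspring = centre + rng.normal(0.0, config.cluster_sigma_um, size=(k, 3))
        np.clip(offspring, 0.0, box, out=offspring)
        parents.append(centre)
        counts.append(k)
        chunks.append(offspring)
        remaining -= k
    positions = np.vstack(chunks) if chunks else np.empty((0, 3))
    parent_centres = np.vstack(parents) if parents else np.empty((0, 3))
    offspring_counts = np.asarray(counts, dtype=np.int64)
    parent_index = np.repeat(np.arange(len(counts), dtype=np.int64), offspring_counts)
    return positions, PositionTruth(parent_centres, parent_index, offspring_counts)


def simulate_positions(n_events: int, config: SynthConfig) -> np.ndarray:
    """Thomas-process event positions (micrometres), shape ``(n_events, 3)``."""
    return _simulate_positions(n_events, config, _positions_rng(config))[0]


def simulate_positions_with_truth(n_events: int, config: SynthConfig) -> tuple[np.ndarray, PositionTruth]:
    """Positions plus the parent bookkeeping used to generate them."""
    return _simulate_positions(n_events, config, _positions_rng(config))


@dataclass
class TableTruth:
    """Per-root generator ground truth for a simulated study."""

    burst_frames: dict[str, list[int]]
    period_h: dict[str, float]
    parents_per_frame: dict[str, dict[int, int]]

    def to_jsonable(self) -> dict:
        return {
            "burst_frames": {r: list(map(int, v)) for r, v in self.burst_frames.items()},
            "period_h": dict(self.period_h),
            "parents_per_frame": {
                r: {str(f): int(m) for f, m in v.items()} for r, v in self.parents_per_frame.items()
            },
        }


def simulate_table_with_truth(
    config_intact: SynthConfig,
    config_regen: SynthConfig,
    n_roots_per_condition: int = 4,
) -> tuple[EventTable, TableTruth]:
    """Simulate a full two-condition study; also return generator truth."""
    if n_roots_per_condition < 1:
        raise ValueError("n_roots_per_condition must be >= 1")
    if config_intact.delta_t_h != config_regen.delta_t_h:
        raise ValueError("conditions must share delta_t_h")

    truth = TableTruth({}, {}, {})
    frames_all: list[np.ndarray] = []
    pos_all: list[np.ndarray] = []
    root_col: list[str] = []
    cond_col: list[str] = []
    ids: list[str] = []

    for ci, (condition, cfg) in enumerate(
        [("intact", config_intact), ("regenerating", config_regen)]
    ):
        for r in range(n_roots_per_condition):
            root_id = f"{condition}_{r + 1}"
            rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, ci, r)))
            counts, burst_frames = _simulate_counts(cfg, rng)
            truth.burst_frames[root_id] = burst_frames.tolist()
            truth.period_h[root_id] = cfg.period_h if cfg.mod_amplitude > 0 else 0.0
            parents: dict[int, int] = {}
            for f in np.flatnonzero(counts):
                pos, ptruth = _simulate_positions(int(counts[f]), cfg, rng)
                parents[int(f)] = ptruth.n_parents
                frames_all.append(np.full(len(pos), f, dtype=np.int64))
                pos_all.append(pos)
                root_col.extend([root_id] * len(pos))
                cond_col.extend([condition] * len(pos))
                ids.extend(f"{root_id}-f{f}-{j}" for j in range(len(pos)))
            truth.parents_per_frame[root_id] = parents

    if pos_all:
        frames = np.concatenate(frames_all)
        pos = np.vstack(pos_all)
    else:
        frames = np.empty(0, dtype=np.int64)
        pos = np.empty((0, 3))
    df = pd.DataFrame(
        {
            "event_id": ids,
            "root_id": root_col,
            "condition": cond_col,
            "frame_index": frames,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
        }
    )
    n_frames = max(config_intact.n_frames, config_regen.n_frames)
    table = EventTable(df, delta_t_h=config_intact.delta_t_h, n_frames=n_frames)
    return table, truth


def simulate_table(
    config_intact: SynthConfig,
    config_regen: SynthConfig,
    n_roots_per_condition: int = 4,
) -> EventTable:
    """Simulate a combined intact + regenerating event table."""
    return simulate_table_with_truth(config_intact, config_regen, n_roots_per_condition)[0]
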