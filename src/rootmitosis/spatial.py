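"""Density-based spatial clustering of per-frame event positions.

Events are clustered frame by frame (never across frames) with DBSCAN on
Euclidean distance in raw micrometre coordinates.  The neighbourhood radius
follows the tissue geometry: a division event is modelled as a 6 x 4 x 4 um
cuboid cell whose maximum diagonal ("diameter") is sqrt(68) ~ 8.24 um, and
two events belong to the same cluster when they lie within three cell
diameters, epsilon = 3 x 8.24 = 24.72 um.  The default ``min_samples`` is 2
(the count includes the point itself), which makes DBSCAN exactly the
connected-components clustering of the epsilon-neighbourhood graph:
singleton events are noise, not size-1 clusters, and are excluded from
cluster-size distributions and centres of mass.

Cluster labels are canonical: clusters are numbered 0, 1, ... in ascending
order of their first member's input index, so the labelling is a pure
function of the point set.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .events_io import EventTable

__all__ = [
    "ARABIDOPSIS_CELL",
    "DEFAULT_EPSILON_UM",
    "CellGeometry",
    "ClusterLabeling",
    "ClusterParams",
    "ClusterSummary",
    "cell_diameter",
    "cluster_count_size_distribution",
    "cluster_table",
    "dbscan",
    "epsilon_from_diameter",
    "pairwise_centre_distances",
    "summarize_clusters",
]


def cell_diameter(dx: float, dy: float, dz: float) -> float:
    """Maximum diagonal of a cuboid cell with edges ``dx, dy, dz`` (um)."""
    if dx < 0 or dy < 0 or dz < 0:
        raise ValueError("cell edges must be non-negative")
    if dx == dy == dz == 0:
        raise ValueError("cell edges must not all be zero")
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@dataclass(frozen=True)
class CellGeometry:
    """Modelled cuboid cell; ``diameter`` is its maximum diagonal."""

    dx: float
    dy: float
    dz: float

    @property
    def diameter(self) -> float:
        return cell_diameter(self.dx, self.dy, self.dz)


#: The 6 x 4 x 4 um meristematic cell model (diameter ~ 8.24 um).
ARABIDOPSIS_CELL = CellGeometry(6.0, 4.0, 4.0)

#: Three cell diameters with the diameter rounded as printed (3 x 8.24).
DEFAULT_EPSILON_UM = 24.72


def epsilon_from_diameter(diameter: float, k: int = 3) -> float:
    """Neighbourhood radius as ``k`` cell diameters (default 3).

    ``epsilon_from_diameter(8.24, 3) == 24.72``; pass the exact diameter
    (``ARABIDOPSIS_CELL.diameter``) for the unrounded variant 3*sqrt(68).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * diameter


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters; ``min_samples`` counts the point itself."""

    epsilon_um: float = DEFAULT_EPSILON_UM
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.epsilon_um <= 0:
            raise ValueError("epsilon_um must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class ClusterLabeling:
    """Per-event cluster labels for one frame; -1 marks noise."""

    labels: np.ndarray
    frame_index: int | None = None
    root_id: str | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size and self.labels.max() >= 0 else 0


def dbscan(points: np.ndarray, params: ClusterParams, *,
           frame_index: int | None = None, root_id: str | None = None) -> ClusterLabeling:
    """DBSCAN with Euclidean distance and deterministic canonical labels.

    A core point has at least ``min_samples`` points (itself included) within
    ``epsilon_um``; clusters are maximal density-connected sets; non-core
    points adjacent to a core point join its cluster, all others are noise.
    Empty input yields an empty labelling.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterLabeling(np.empty(0, dtype=np.int64), frame_index, root_id)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")

    n = len(pts)
    tree = cKDTree(pts)
    neigh = tree.query_ball_point(pts, r=params.epsilon_um)
    core = np.array([len(nb) >= params.min_samples for nb in neigh])

    labels = np.full(n, -1, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for nb in sorted(neigh[j]):
                if labels[nb] == -1:
                    labels[nb] = cluster
                    if core[nb]:
                        queue.append(nb)
        cluster += 1

    # canonical numbering: ascending order of each cluster's first member
    if cluster > 1:
        first = np.full(cluster, n, dtype=np.int64)
        for i in range(n - 1, -1, -1):
            if labels[i] >= 0:
                first[labels[i]] = i
        order = np.argsort(first, kind="stable")
        remap = np.empty(cluster, dtype=np.int64)
        remap[order] = np.arange(cluster)
        labels[labels >= 0] = remap[labels[labels >= 0]]
    return ClusterLabeling(labels, frame_index, root_id)


@dataclass
class ClusterSummary:
    """Cluster count, sizes and centres of mass for one frame."""

    frame_index: int | None
    n_clusters: int
    sizes: np.ndarray            # member count per cluster, by label
    centres: np.ndarray          # (n_clusters, 3) unweighted mean positions
    root_id: str | None = None


def summarize_clusters(labeling: ClusterLabeling, points: np.ndarray) -> ClusterSummary:
    """Sizes and unweighted centres of mass of the non-noise clusters."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    labels = labeling.labels
    if len(labels) != len(pts):
        raise ValueError("labeling inconsistent with points")
    k = labeling.n_clusters
    sizes = np.zeros(k, dtype=np.int64)
    centres = np.zeros((k, 3))
    for c in range(k):
        member = labels == c
        sizes[c] = member.sum()
        centres[c] = pts[member].mean(axis=0)
    return ClusterSummary(labeling.frame_index, k, sizes, centres, labeling.root_id)


def cluster_count_size_distribution(summaries: Iterable[ClusterSummary]) -> pd.DataFrame:
    """Joint frequency of (clusters in frame, cluster size) over all frames.

    Each frame contributes one entry per cluster: the pair
    ``(that frame's n_clusters, that cluster's size)``.  Frames without
    clusters contribute nothing.  Returns columns
    ``n_clusters, size, frequency``.
    """
    pairs: dict[tuple[int, int], int] = {}
    for s in summaries:
        for size in s.sizes:
            key = (int(s.n_clusters), int(size))
            pairs[key] = pairs.get(key, 0) + 1
    rows = sorted(pairs.items())
    return pd.DataFrame(
        {
            "n_clusters": [k[0] for k, _ in rows],
            "size": [k[1] for k, _ in rows],
            "frequency": [v for _, v in rows],
        }
    )


def pairwise_centre_distances(summary: ClusterSummary) -> np.ndarray:
    """All C(k, 2) Euclidean distances between cluster centres in a frame."""
    if summary.n_clusters < 2:
        return np.empty(0)
    return pdist(summary.centres)


def cluster_table(
    table: EventTable, params: ClusterParams = ClusterParams()
) -> tuple[pd.DataFrame, list[ClusterSummary]]:
    """Cluster every (root, frame) point set of an event table.

    Returns a per-event label frame (``event_id, root_id, condition,
    frame_index, label``) and the list of per-frame cluster summaries,
    ordered by root then frame.
    """
    ev = table.events
    label_col = np.full(len(ev), -1, dtype=np.int64)
    summaries: list[ClusterSummary] = []
    for (root_id, frame), idx in ev.groupby(["root_id", "frame_index"], sort=True).indices.items():
        pts = ev.iloc[idx][["x_um", "y_um", "z_um"]].to_numpy()
        lab = dbscan(pts, params, frame_index=int(frame), root_id=str(root_id))
        label_col[idx] = lab.labels
        summaries.append(summarize_clusters(lab, pts))
    labels_df = ev[["event_id", "root_id", "condition", "frame_index"]].copy()
    labels_df["label"] = label_col
    return labels_df, summaries
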