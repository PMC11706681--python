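"""Mitotic-event tables: reading, validation, time conversion and temporal binning.

A table holds one row per detected cell-division event — the 3D centre of
mass of a transient cell-cycle-reporter signal — together with the root it
came from, its condition label (``intact`` or ``regenerating``), and the
time-lapse frame it was detected in.  Time in hours is derived from the
frame index and the sampling interval ``delta_t_h`` (0.25 h, i.e. one image
stack every 15 minutes, by default); the frame index is always the
authoritative quantity and ``time_h`` is recomputed on read.

Coordinates are absolute micrometres in the microscope frame.  The imaged
tissue has no persistent landmark across frames, so positions are only ever
used through relative distances and no coordinate normalisation is applied.

Post-perturbation analyses slice events into the four temporal bins
[0, 6), [6, 24), [24, 72) and [72, inf) hours.  Bins are half-open so that
every non-negative time belongs to exactly one bin (a time of exactly 6 h
falls in the 6-24 h bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "TIME_BINS",
    "BIN_BY_LABEL",
    "EventTable",
    "MitoticEvent",
    "RowValidationError",
    "SchemaError",
    "TimeBin",
    "assign_time_bins",
    "read_events",
    "time_bin_of",
    "write_events",
]

#: Canonical column order of the on-disk event table.
COLUMNS = [
    "event_id",
    "root_id",
    "condition",
    "frame_index",
    "time_h",
    "x_um",
    "y_um",
    "z_um",
]

_REQUIRED = ("root_id", "condition", "frame_index")
_COORDS = ("x_um", "y_um", "z_um")
_COORD_ALIASES = {"x": "x_um", "y": "y_um", "z": "z_um"}


class SchemaError(ValueError):
    """A required column is missing from an event-table file."""


class RowValidationError(ValueError):
    """A row of an event-table file violates the data contract."""


@dataclass(frozen=True)
class TimeBin:
    """Half-open temporal analysis window ``[lower_h, upper_h)`` in hours."""

    label: str
    lower_h: float
    upper_h: float  # math.inf for the unbounded last bin

    def contains(self, time_h: float) -> bool:
        return self.lower_h <= time_h < self.upper_h


#: Post-perturbation analysis windows; they partition [0, inf).
TIME_BINS: tuple[TimeBin, ...] = (
    TimeBin("0-6h", 0.0, 6.0),
    TimeBin("6-24h", 6.0, 24.0),
    TimeBin("24-72h", 24.0, 72.0),
    TimeBin(">72h", 72.0, math.inf),
)

BIN_BY_LABEL = {b.label: b for b in TIME_BINS}


def time_bin_of(time_h: float) -> TimeBin:
    """Return the unique temporal bin containing ``time_h`` (hours, >= 0)."""
    if not np.isfinite(time_h) or time_h < 0:
        raise ValueError(f"time_h must be finite and non-negative, got {time_h!r}")
    for b in TIME_BINS:
        if b.contains(time_h):
            return b
    raise AssertionError("unreachable: bins cover [0, inf)")


@dataclass(frozen=True)
class MitoticEvent:
    """One detected division event (centre of mass in micrometres)."""

    event_id: str
    root_id: str
    condition: str
    frame_index: int
    time_h: float
    x_um: float
    y_um: float
    z_um: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um])


@dataclass
class EventTable:
    """Validated collection of mitotic events on a fixed frame grid.

    Parameters
    ----------
    events
        DataFrame with at least ``root_id``, ``condition``, ``frame_index``
        and the three coordinate columns.  ``event_id`` is generated and
        ``time_h`` recomputed if absent or inconsistent.
    delta_t_h
        Sampling interval in hours per frame (default 0.25 = 15 min).
    n_frames
        Length of the frame grid; defaults to ``1 + max(frame_index)``
        (0 for an empty table).
    """

    events: pd.DataFrame
    delta_t_h: float = 0.25
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if not self.delta_t_h > 0:
            raise ValueError(f"delta_t_h must be positive, got {self.delta_t_h}")
        df = self.events.copy()
        df = df.rename(columns={a: c for a, c in _COORD_ALIASES.items() if c not in df.columns})
        for col in _REQUIRED + _COORDS:
            if col not in df.columns:
                raise SchemaError(f"missing required column '{col}'")
        if "event_id" not in df.columns:
            df["event_id"] = [f"e{i:06d}" for i in range(len(df))]
        df["event_id"] = df["event_id"].astype(str)
        df["root_id"] = df["root_id"].astype(str)
        df["condition"] = df["condition"].astype(str)

        frames = pd.to_numeric(df["frame_index"], errors="coerce")
        bad = frames.isna() | (frames < 0) | (frames != frames.round())
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowValidationError(
                f"row {i}: frame_index must be a non-negative integer, "
                f"got {df['frame_index'].iloc[i]!r}"
            )
        df["frame_index"] = frames.astype(np.int64)

        for col in _COORDS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | ~np.isfinite(vals)
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise RowValidationError(
                    f"row {i}: column '{col}' must be a finite number, got {df[col].iloc[i]!r}"
                )
            # astype (not to_numeric) for a correctly rounded parse, so that
            # write -> read -> write is byte-stable
            df[col] = df[col].astype(np.float64)

        # frame_index is authoritative; time follows the frame grid exactly.
        df["time_h"] = df["frame_index"].to_numpy() * self.delta_t_h

        if df["event_id"].duplicated().any():
            dup = df["event_id"][df["event_id"].duplicated()].iloc[0]
            raise RowValidationError(f"duplicate event_id {dup!r}")

        min_frames = 0 if df.empty else int(df["frame_index"].max()) + 1
        if self.n_frames is None:
            self.n_frames = min_frames
        elif self.n_frames < min_frames:
            raise ValueError(
                f"n_frames={self.n_frames} smaller than 1 + max frame_index ({min_frames})"
            )
        self.events = df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.events["condition"].unique())

    @property
    def root_ids(self) -> list[str]:
        return sorted(self.events["root_id"].unique())

    def condition_of(self, root_id: str) -> str:
        sub = self.events.loc[self.events["root_id"] == root_id, "condition"]
        if sub.empty:
            raise KeyError(f"unknown root_id {root_id!r}")
        return str(sub.iloc[0])

    def for_root(self, root_id: str) -> pd.DataFrame:
        if root_id not in set(self.events["root_id"]):
            raise KeyError(f"unknown root_id {root_id!r}")
        return self.events[self.events["root_id"] == root_id]

    def for_condition(self, condition: str) -> "EventTable":
        sub = self.events[self.events["condition"] == condition]
        return EventTable(sub.reset_index(drop=True), self.delta_t_h, self.n_frames)

    def iter_events(self) -> Iterator[MitoticEvent]:
        for row in self.events.itertuples(index=False):
            yield MitoticEvent(
                row.event_id, row.root_id, row.condition,
                int(row.frame_index), float(row.time_h),
                float(row.x_um), float(row.y_um), float(row.z_um),
            )

    def equals(self, other: "EventTable") -> bool:
        return (
            self.delta_t_h == other.delta_t_h
            and self.n_frames == other.n_frames
            and self.events.equals(other.events)
        )


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_events(path: str | Path, delta_t_h: float = 0.25, n_frames: int | None = None) -> EventTable:
    """Read a delimited event table (comma or tab, auto-detected).

    The header must name at least ``root_id``, ``condition``, ``frame_index``
    and the coordinates (``x_um``/``y_um``/``z_um`` or bare ``x``/``y``/``z``).
    ``time_h`` is recomputed from ``frame_index * delta_t_h``.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return EventTable(df, delta_t_h=delta_t_h, n_frames=n_frames)


def write_events(table: EventTable, path: str | Path) -> None:
    """Write a table as comma-delimited text; round-trips through `read_events`."""
    table.events[COLUMNS].to_csv(path, index=False, encoding="utf-8")


def assign_time_bins(table: EventTable) -> pd.Series:
    """Map every event to its temporal bin label.

    Returns a Series of bin labels (see :data:`TIME_BINS`) indexed by
    ``event_id``; look up the full :class:`TimeBin` via :data:`BIN_BY_LABEL`.
    """
    times = table.events["time_h"].to_numpy()
    edges = [b.lower_h for b in TIME_BINS] + [math.inf]
    idx = np.searchsorted(edges, times, side="right") - 1
    labels = np.array([b.label for b in TIME_BINS], dtype=object)[idx]
    return pd.Series(labels, index=pd.Index(table.events["event_id"], name="event_id"), name="time_bin")
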