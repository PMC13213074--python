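"""Fraction-of-frames interaction statistics.

Contact frequencies and hydrogen-bond occupancies are the percentage of
trajectory frames in which a geometric criterion is met.  The geometry
itself (donor-acceptor distances, angles) is delegated to standard
trajectory tooling; this module consumes precomputed distance series or
boolean event series and computes the occupancy statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OccupancySeries", "contact_frequency", "occupancy_percent",
           "read_event_table"]


@dataclass
class OccupancySeries:
    """Per-frame boolean events (criterion met) with an optional description."""

    events: np.ndarray
    criterion: str = ""
    times_ns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events).astype(bool)
        if self.times_ns is not None:
            self.times_ns = np.asarray(self.times_ns, dtype=float)
            if len(self.times_ns) != len(self.events):
                raise ValueError("times_ns length does not match events")

    def __len__(self) -> int:
        return len(self.events)


def contact_frequency(distances, cutoff: float) -> float:
    """Fraction of frames with distance strictly below *cutoff* (A)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return float((d < cutoff).mean())


def occupancy_percent(events) -> float:
    """100 x (frames meeting the criterion / total frames)."""
    if isinstance(events, OccupancySeries):
        e = events.events
    else:
        e = np.asarray(events).astype(bool)
    if e.size == 0:
        raise ValueError("empty event series")
    return float(100.0 * e.mean())


def read_event_table(path, column: str = "event") -> OccupancySeries:
    """Read a CSV of per-frame 0/1 events (columns ``frame,event``)."""
    df = pd.read_csv(path)
    if column not in df.columns:
        raise ValueError(f"missing column {column!r} in {path}")
    vals = pd.to_numeric(df[column], errors="coerce")
    if vals.isna().any():
        lines = (df.index[vals.isna()] + 2).tolist()
        raise ValueError(f"non-numeric event cells at line(s): {lines}")
    if not set(np.unique(vals)) <= {0, 1}:
        raise ValueError("event column must contain only 0/1 values")
    times = df["time_ns"].to_numpy(dtype=float) if "time_ns" in df.columns else None
    return OccupancySeries(events=vals.to_numpy(), times_ns=times)
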