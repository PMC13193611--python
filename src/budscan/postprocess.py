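"""Frame probabilities -> discrete division events, lifespan and cycle series.

A frame is called positive when its budding probability reaches the
threshold; consecutive positive calls are merged into a single division event
(so a bud seen across several frames is counted once), the replicative
lifespan is the number of events, and successive event gaps give the
cell-cycle-length series over the cell's life.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DivisionTimeline
from .detector import FrameProbabilities

__all__ = [
    "BinaryCallSequence",
    "CellCycleSeries",
    "binarize",
    "collapse_runs",
    "compute_rls",
    "cell_cycle_lengths",
]


@dataclass(frozen=True)
class BinaryCallSequence:
    cell_id: str
    calls: np.ndarray  # (T,) of 0/1
    threshold: float

    def __post_init__(self):
        c = np.asarray(self.calls, dtype=np.int64)
        if not np.isin(c, (0, 1)).all():
            raise ValueError("calls must be 0/1")
        object.__setattr__(self, "calls", c)


@dataclass(frozen=True)
class CellCycleSeries:
    """Per-cycle intervals: (event index, gap frames, gap minutes, % of
    lifespan, nondecreasing with cycle order)."""

    cell_id: str
    intervals: tuple[tuple[int, int, float, float], ...]


def binarize(probs: FrameProbabilities, threshold: float) -> BinaryCallSequence:
    """Elementwise comparison: call = 1 iff prob >= threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    return BinaryCallSequence(cell_id=probs.cell_id,
                              calls=(probs.probs >= threshold).astype(np.int64),
                              threshold=threshold)


def collapse_runs(calls: BinaryCallSequence, representative: str = "first",
                  min_gap: int = 0) -> DivisionTimeline:
    """Merge each maximal run of consecutive positive calls into one event.

    The representative frame of a run is its first frame (bud-emergence
    semantics) or, with ``representative="midpoint"``, the run's middle
    frame. ``min_gap > 0`` optionally drops any event closer than ``min_gap``
    frames to the previous kept event (off by default: merging only).
    """
    if representative not in ("first", "midpoint"):
        raise ValueError("representative must be 'first' or 'midpoint'")
    c = calls.calls
    padded = np.concatenate([[0], c, [0]])
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1)  # exclusive
    if representative == "first":
        events = starts
    else:
        events = (starts + ends - 1) // 2
    if min_gap > 0 and len(events):
        kept = [int(events[0])]
        for e in events[1:]:
            if e - kept[-1] >= min_gap:
                kept.append(int(e))
        events = np.asarray(kept)
    return DivisionTimeline(cell_id=calls.cell_id,
                            event_frames=tuple(int(e) for e in events),
                            n_frames=len(c))


def compute_rls(timeline: DivisionTimeline) -> int:
    """Replicative lifespan: the number of detected division events."""
    return timeline.rls


def cell_cycle_lengths(timeline: DivisionTimeline,
                       frame_interval_min: float | None = None) -> CellCycleSeries:
    """Inter-division intervals with timing metadata.

    Interval ``k`` spans events ``k`` and ``k+1``; its position along the
    cell's life is ``100 * k / (RLS - 1)`` percent (the lifespan-fraction
    axis used for cycle-length trajectories). Fewer than two events give an
    empty series.
    """
    interval = frame_interval_min if frame_interval_min is not None else timeline.frame_interval_min
    ev = timeline.event_frames
    if len(ev) < 2:
        return CellCycleSeries(cell_id=timeline.cell_id, intervals=())
    denom = len(ev) - 1  # interval k of RLS-1 sits at 100*k/(RLS-1) percent
    rows = []
    for k, (a, b) in enumerate(zip(ev, ev[1:])):
        gap = b - a
        rows.append((k, gap, gap * interval, 100.0 * k / denom))
    return CellCycleSeries(cell_id=timeline.cell_id, intervals=tuple(rows))
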