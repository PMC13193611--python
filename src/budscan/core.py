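"""Shared domain types for division timelines."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DivisionTimeline:
    """Per-cell record of division (bud-emergence) events.

    ``event_frames`` are 0-based frame indices, strictly increasing; the
    replicative lifespan (RLS) of the cell is their count. ``n_frames`` is the
    total movie length when known (``None`` for annotation files read without
    an accompanying movie).
    """

    cell_id: str
    event_frames: tuple[int, ...]
    n_frames: int | None = None
    frame_interval_min: float = 15.0

    def __post_init__(self):
        ev = tuple(int(e) for e in self.event_frames)
        object.__setattr__(self, "event_frames", ev)
        if any(b <= a for a, b in zip(ev, ev[1:])):
            raise ValueError(f"{self.cell_id}: event frames must be strictly increasing: {ev}")
        if ev and ev[0] < 0:
            raise ValueError(f"{self.cell_id}: negative event frame {ev[0]}")
        if self.n_frames is not None and ev and ev[-1] >= self.n_frames:
            raise ValueError(
                f"{self.cell_id}: event frame {ev[-1]} outside movie of {self.n_frames} frames"
            )

    @property
    def rls(self) -> int:
        """Replicative lifespan: the number of division events."""
        return len(self.event_frames)

    def gaps(self) -> list[int]:
        """Inter-division intervals in frames (length RLS - 1)."""
        return [b - a for a, b in zip(self.event_frames, self.event_frames[1:])]
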