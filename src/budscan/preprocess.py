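"""Crop extraction, normalization, temporal stacking and cell-exclusive splits.

The pipeline convention: a 224 x 224 px region is cropped around each tracked
mother-cell centroid, resized to 64 x 64 px, z-scored with dataset-level
statistics computed on training cells only, and assembled into 11-frame
temporal stacks (the frame of interest with five preceding and five
subsequent frames). Movie boundaries are handled by edge replication so every
frame receives a stack (and later a prediction); replicated slots are flagged.

All frame indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .core import DivisionTimeline

__all__ = [
    "FrameCrop",
    "TemporalStack",
    "SplitAssignment",
    "NormStats",
    "center_crop",
    "resize_and_normalize",
    "compute_norm_stats",
    "normalize_movie",
    "build_stacks",
    "label_stacks",
    "split_by_cell",
    "window_indices",
]

HALF_WINDOW = 5
WINDOW = 2 * HALF_WINDOW + 1


@dataclass(frozen=True)
class NormStats:
    """Dataset-level z-score statistics, computed on training cells only."""

    mean: float
    std: float

    def __post_init__(self):
        if not (np.isfinite(self.mean) and np.isfinite(self.std)):
            raise ValueError("normalization statistics must be finite")
        if self.std <= 0:
            raise ValueError("normalization std must be positive")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) - self.mean) / self.std


@dataclass(frozen=True)
class FrameCrop:
    """One normalized crop of a tracked mother cell at one time point."""

    cell_id: str
    frame_index: int
    pixels: np.ndarray
    source_crop_size: int = 224
    target_size: int = 64

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.shape != (self.target_size, self.target_size):
            raise ValueError(f"crop shape {px.shape} != ({self.target_size}, {self.target_size})")
        if not np.isfinite(px).all():
            raise ValueError("crop contains non-finite pixels")


@dataclass(frozen=True)
class TemporalStack:
    """An 11-slot temporal window around ``center_frame``.

    ``frame_indices`` are the source frame indices of each slot (clipped at
    the movie boundary), ``padding_flags`` marks slots that are boundary
    replications, and ``label`` is 1 when a budding event occurs at the
    center frame (``None`` at inference).
    """

    cell_id: str
    center_frame: int
    frame_indices: tuple[int, ...]
    padding_flags: tuple[bool, ...]
    label: int | None = None

    def __post_init__(self):
        if len(self.frame_indices) != WINDOW or len(self.padding_flags) != WINDOW:
            raise ValueError(f"a temporal stack has exactly {WINDOW} slots")
        if list(self.frame_indices) != sorted(self.frame_indices):
            raise ValueError("stack slots must be temporally ordered")


@dataclass(frozen=True)
class SplitAssignment:
    train_cells: frozenset[str]
    val_cells: frozenset[str]
    train_frac: float
    seed: int

    def __post_init__(self):
        if self.train_cells & self.val_cells:
            raise ValueError("train/validation cell sets must be disjoint")


def center_crop(frame: np.ndarray, centroid: tuple[float, float], size: int) -> np.ndarray:
    """Crop a ``size`` x ``size`` region centered on ``centroid`` (row, col).

    The crop lies on the integer pixel grid (no interpolation); regions
    falling outside the frame are filled by edge replication.
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    if size > 2 * h or size > 2 * w:
        raise ValueError(f"crop size {size} exceeds twice the frame extent {(h, w)}")
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"centroid {centroid} outside frame of shape {(h, w)}")
    r0, c0 = r - size // 2, c - size // 2
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + size - h)
    pad_right = max(0, c0 + size - w)
    if pad_top or pad_left or pad_bottom or pad_right:
        frame = np.pad(frame, ((pad_top, pad_bottom), (pad_left, pad_right)), mode="edge")
        r0 += pad_top
        c0 += pad_left
    return frame[r0:r0 + size, c0:c0 + size]


def resize_and_normalize(crop: np.ndarray, target: int, stats: NormStats,
                         cell_id: str = "", frame_index: int = 0) -> FrameCrop:
    """Bilinear-resize a crop to ``target`` x ``target`` and z-score it."""
    crop = np.asarray(crop, dtype=np.float64)
    if crop.shape != (target, target):
        crop = _sk_resize(crop, (target, target), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    return FrameCrop(cell_id=cell_id, frame_index=frame_index,
                     pixels=stats.apply(crop),
                     source_crop_size=crop.shape[0], target_size=target)


def compute_norm_stats(movies: dict[str, np.ndarray], train_cells) -> NormStats:
    """Dataset mean/std over all frames of the training cells."""
    train_cells = set(train_cells)
    frames = [movies[c] for c in movies if c in train_cells]
    if not frames:
        raise ValueError("no training cells found in the provided movies")
    stacked = np.concatenate([np.asarray(f, dtype=np.float64).ravel() for f in frames])
    return NormStats(mean=float(stacked.mean()), std=float(stacked.std()))


def normalize_movie(movie: np.ndarray, stats: NormStats) -> np.ndarray:
    return stats.apply(movie)


def window_indices(T: int, center: int, half_window: int = HALF_WINDOW
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices and padding flags of the window around ``center``."""
    raw = np.arange(center - half_window, center + half_window + 1)
    clipped = np.clip(raw, 0, T - 1)
    return clipped, raw != clipped


def build_stacks(cell_id: str, n_frames: int,
                 half_window: int = HALF_WINDOW) -> list[TemporalStack]:
    """One temporal stack per frame of a movie, with boundary replication."""
    if n_frames < 1:
        raise ValueError("movies must have at least one frame")
    stacks = []
    for center in range(n_frames):
        idx, pad = window_indices(n_frames, center, half_window)
        stacks.append(TemporalStack(cell_id=cell_id, center_frame=center,
                                    frame_indices=tuple(int(i) for i in idx),
                                    padding_flags=tuple(bool(p) for p in pad)))
    return stacks


def label_stacks(stacks: list[TemporalStack], timeline: DivisionTimeline,
                 positive_span: int = 1) -> list[TemporalStack]:
    """Attach binary labels: 1 iff the center frame falls within
    ``positive_span`` frames at/after an annotated event frame (span 1 means
    the event frame only)."""
    if positive_span < 1:
        raise ValueError("positive_span must be >= 1")
    if stacks:
        T = max(s.center_frame for s in stacks) + 1
        for e in timeline.event_frames:
            if not (0 <= e < T):
                raise ValueError(f"event frame {e} outside movie of {T} frames")
    events = np.asarray(timeline.event_frames)
    out = []
    for s in stacks:
        pos = bool(events.size) and bool(
            ((events <= s.center_frame) & (s.center_frame < events + positive_span)).any())
        out.append(TemporalStack(cell_id=s.cell_id, center_frame=s.center_frame,
                                 frame_indices=s.frame_indices,
                                 padding_flags=s.padding_flags, label=int(pos)))
    return out


def split_by_cell(cell_ids, train_frac: float = 0.8, seed: int = 0) -> SplitAssignment:
    """Randomly partition cells into train/validation, cell-exclusively.

    Every frame of a cell follows its cell's assignment, so no cell
    contributes to both splits. ``|train| = round(train_frac * n)``.
    """
    cells = sorted(set(cell_ids))
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to split")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cells))
    n_train = int(round(train_frac * len(cells)))
    n_train = min(max(n_train, 1), len(cells) - 1)  # both splits stay nonempty
    train = frozenset(cells[i] for i in perm[:n_train])
    val = frozenset(cells[i] for i in perm[n_train:])
    return SplitAssignment(train_cells=train, val_cells=val,
                           train_frac=train_frac, seed=seed)
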