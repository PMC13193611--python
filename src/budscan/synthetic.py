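"""Synthetic mother-machine movies with known division schedules.

Emulates lifelong phase-contrast imaging of a single trapped yeast mother
cell: a bright elliptical mother body sits in a fixed trap position, buds
emerge on the channel-facing side at scheduled frames, grow over a few frames
and are then flushed away by the medium flow. Division schedules reproduce
the qualitative structure of replicative aging — rapid budding in young cells
followed by progressive late-life cell-cycle lengthening — with configurable
pixel noise, sub-pixel position jitter and frame-to-frame illumination
fluctuations.

Every operation is a pure function of its parameters and seed, so the
generated ground truth (per-frame bud masks and event frames) is exact and
the whole downstream pipeline is testable without microscopy data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import tifffile

from .core import DivisionTimeline

__all__ = [
    "ScheduleParams",
    "SyntheticCellSpec",
    "sample_division_schedule",
    "render_cell_movie",
    "write_fixture_dataset",
]

_JITTER_CLIP_SIGMAS = 3.0  # jitter offsets are clipped at ±3 sigma


@dataclass(frozen=True)
class ScheduleParams:
    """Statistical description of a division schedule.

    rls_mean/rls_sd
        Mean and SD of the per-cell replicative lifespan (events); the drawn
        RLS is rounded and floored at 1.
    base_cycle_frames
        Expected inter-division gap for a young cell, in frames (default 6,
        i.e. a 90-minute cycle at 15-minute sampling).
    late_life_slowdown
        Multiplicative factor (>= 1) by which the expected gap lengthens by
        the end of life; applied as a linear ramp over event index.
    cycle_noise_sd
        SD of per-gap Gaussian noise, in frames; drawn gaps are floored at 1.
    """

    rls_mean: float = 15.0
    rls_sd: float = 4.0
    base_cycle_frames: float = 6.0
    late_life_slowdown: float = 2.0
    cycle_noise_sd: float = 1.0

    def validate(self):
        if self.base_cycle_frames < 1:
            raise ValueError("base_cycle_frames must be >= 1 (zero-length cycles rejected)")
        if self.late_life_slowdown < 1:
            raise ValueError("late_life_slowdown must be >= 1")
        if self.rls_mean < 1:
            raise ValueError("rls_mean must be >= 1")
        if self.rls_sd < 0 or self.cycle_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Geometry and imaging parameters of one synthetic mother cell."""

    cell_id: str = "cell"
    image_size: int = 64
    mother_center: tuple[float, float] = (36.0, 32.0)  # (row, col); trap wall at bottom
    mother_radii: tuple[float, float] = (10.0, 8.0)
    mother_intensity: float = 0.75
    background_intensity: float = 0.2
    noise_sigma: float = 0.05
    jitter_sigma: float = 0.3
    bud_growth_frames: int = 4
    bud_max_radius: float = 5.0
    illumination_scale: float = 1.05
    bud_angle_jitter: float = 0.25  # radians around the channel-facing direction
    rng_seed: int = 0

    def validate(self):
        if self.bud_growth_frames < 1:
            raise ValueError("bud_growth_frames must be >= 1")
        if self.bud_max_radius >= min(self.mother_radii):
            raise ValueError("bud_max_radius must be smaller than the mother radii")
        if self.illumination_scale <= 0:
            raise ValueError("illumination_scale must be positive")
        jit = _JITTER_CLIP_SIGMAS * self.jitter_sigma
        r, c = self.mother_center
        rr, rc = self.mother_radii
        n = self.image_size
        if not (r - rr - jit >= 0 and r + rr + jit < n and c - rc - jit >= 0 and c + rc + jit < n):
            raise ValueError("mother ellipse must stay inside the image after maximal jitter")


def sample_division_schedule(params: ScheduleParams, seed: int,
                             tail_frames: int = 20) -> DivisionTimeline:
    """Draw one cell's division schedule.

    The expected gap before event ``k`` (of ``rls`` total) ramps linearly from
    ``base_cycle_frames`` to ``base_cycle_frames * late_life_slowdown`` across
    the cell's life, emulating late-life cell-cycle lengthening. Gaussian
    noise of SD ``cycle_noise_sd`` is added per gap and gaps are floored at
    1 frame. The movie extends ``tail_frames`` (default 20, i.e. 5 h at
    15-min sampling) beyond the last event: mother-machine acquisitions run
    until and past division cessation, so every cell ends with a bud-free
    post-cessation period. Frame 0 is never an event frame.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    rls = max(1, int(round(rng.normal(params.rls_mean, params.rls_sd))))
    denom = max(rls - 1, 1)
    events: list[int] = []
    frame = 0
    for k in range(rls):
        ramp = 1.0 + (params.late_life_slowdown - 1.0) * (k / denom)
        expected = params.base_cycle_frames * ramp
        gap = max(1, int(round(rng.normal(expected, params.cycle_noise_sd))))
        frame += gap
        events.append(frame)
    cell_id = f"synthetic-seed{seed}"
    return DivisionTimeline(cell_id=cell_id, event_frames=tuple(events),
                            n_frames=events[-1] + tail_frames)


def _disk_mask(n: int, center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def render_cell_movie(spec: SyntheticCellSpec, timeline: DivisionTimeline,
                      on_overlap: str = "raise") -> tuple[np.ndarray, np.ndarray]:
    """Render a movie and its per-frame ground-truth bud masks.

    Returns ``(movie, bud_pixel_log)``: ``movie`` is a float array of shape
    (T, n, n) with intensities clipped to [0, 1]; ``bud_pixel_log`` is the
    boolean (T, n, n) mask of bud pixels, nonempty exactly on the frames of
    each bud episode (event frame through ``bud_growth_frames`` frames).

    Bud episodes that would overlap (inter-event gap shorter than
    ``bud_growth_frames``) raise ``ValueError`` by default; with
    ``on_overlap="truncate"`` the earlier episode is cut short at the next
    event frame (the choice taken is visible in the returned mask log).
    """
    spec.validate()
    if timeline.n_frames is None or timeline.n_frames < 1:
        raise ValueError("timeline must carry a positive n_frames")
    if on_overlap not in ("raise", "truncate"):
        raise ValueError("on_overlap must be 'raise' or 'truncate'")
    T, n = timeline.n_frames, spec.image_size
    events = timeline.event_frames
    for a, b in zip(events, events[1:]):
        if b - a < spec.bud_growth_frames and on_overlap == "raise":
            raise ValueError(
                f"bud episodes overlap (gap {b - a} < bud_growth_frames "
                f"{spec.bud_growth_frames}); pass on_overlap='truncate' to cut the earlier episode"
            )

    rng = np.random.default_rng(spec.rng_seed)
    # Per-episode bud direction: channel-facing side (decreasing row) with
    # small angular jitter, so daughters emerge into the flow channel.
    angles = -np.pi / 2 + rng.normal(0.0, spec.bud_angle_jitter, size=len(events))
    jitter = np.clip(rng.normal(0.0, spec.jitter_sigma, size=(T, 2)),
                     -_JITTER_CLIP_SIGMAS * spec.jitter_sigma,
                     _JITTER_CLIP_SIGMAS * spec.jitter_sigma)
    s = spec.illumination_scale
    illum = np.exp(rng.uniform(-np.log(s), np.log(s), size=T))
    noise = rng.normal(0.0, spec.noise_sigma, size=(T, n, n)) if spec.noise_sigma > 0 else None

    movie = np.empty((T, n, n), dtype=np.float32)
    bud_log = np.zeros((T, n, n), dtype=bool)
    r_row, r_col = spec.mother_radii
    for t in range(T):
        center = (spec.mother_center[0] + jitter[t, 0], spec.mother_center[1] + jitter[t, 1])
        frame = np.full((n, n), spec.background_intensity, dtype=np.float64)
        frame[_disk_mask(n, center, spec.mother_radii)] = spec.mother_intensity
        for e_idx, e in enumerate(events):
            end = e + spec.bud_growth_frames
            if e_idx + 1 < len(events):
                end = min(end, events[e_idx + 1])  # truncation (only reached when allowed)
            if not (e <= t < end):
                continue
            frac = (t - e + 1) / spec.bud_growth_frames
            bud_r = spec.bud_max_radius * frac
            ang = angles[e_idx]
            # bud touches the mother boundary along the episode direction
            boundary = 1.0 / np.sqrt((np.cos(ang) / r_col) ** 2 + (np.sin(ang) / r_row) ** 2)
            dist = boundary + bud_r
            bud_center = (center[0] + dist * np.sin(ang), center[1] + dist * np.cos(ang))
            mask = _disk_mask(n, bud_center, (bud_r, bud_r))
            frame[mask] = spec.mother_intensity
            bud_log[t] |= mask
        frame *= illum[t]
        if noise is not None:
            frame += noise[t]
        movie[t] = np.clip(frame, 0.0, 1.0)
    return movie, bud_log


def write_fixture_dataset(n_cells: int, params: ScheduleParams,
                          spec_template: SyntheticCellSpec, out_dir: str | os.PathLike,
                          seed: int, overwrite: bool = False,
                          on_overlap: str = "truncate") -> pd.DataFrame:
    """Write a complete on-disk fixture dataset and return its manifest.

    Produces, under ``out_dir``: one 16-bit multi-page TIFF per cell
    (``<cell_id>.tif``, one page per 15-min frame), ``annotations.csv``
    (``cell_id,event_frame``, 0-based), ``tracking.csv``
    (``cell_id,frame,centroid_row,centroid_col``) and ``manifest.csv``
    (``cell_id,tiff_path,n_frames,rls``). Intensities in [0, 1] are scaled by
    65535 so readers must apply the 16-bit normalization.
    """
    out_dir = os.fspath(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True to replace it")
    os.makedirs(out_dir, exist_ok=True)

    seeds = np.random.SeedSequence(seed).generate_state(2 * n_cells)
    manifest_rows, ann_rows, trk_rows = [], [], []
    for i in range(n_cells):
        cell_id = f"cell_{i:03d}"
        timeline = sample_division_schedule(params, int(seeds[2 * i]) % (2 ** 31))
        timeline = replace(timeline, cell_id=cell_id)
        spec = replace(spec_template, cell_id=cell_id, rng_seed=int(seeds[2 * i + 1]) % (2 ** 31))
        movie, _ = render_cell_movie(spec, timeline, on_overlap=on_overlap)
        tiff_path = os.path.join(out_dir, f"{cell_id}.tif")
        tifffile.imwrite(tiff_path, (movie * 65535.0 + 0.5).astype(np.uint16),
                         photometric="minisblack")
        manifest_rows.append((cell_id, tiff_path, timeline.n_frames, timeline.rls))
        ann_rows += [(cell_id, e) for e in timeline.event_frames]
        trk_rows += [(cell_id, t, spec.mother_center[0], spec.mother_center[1])
                     for t in range(timeline.n_frames)]

    manifest = pd.DataFrame(manifest_rows, columns=["cell_id", "tiff_path", "n_frames", "rls"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    pd.DataFrame(ann_rows, columns=["cell_id", "event_frame"]).to_csv(
        os.path.join(out_dir, "annotations.csv"), index=False)
    pd.DataFrame(trk_rows, columns=["cell_id", "frame", "centroid_row", "centroid_col"]).to_csv(
        os.path.join(out_dir, "tracking.csv"), index=False)
    return manifest


def simulate_cells(n_cells: int, params: ScheduleParams, spec_template: SyntheticCellSpec,
                   seed: int, on_overlap: str = "truncate",
                   event_free: bool = False) -> dict[str, tuple[np.ndarray, DivisionTimeline]]:
    """In-memory version of :func:`write_fixture_dataset`.

    Returns ``{cell_id: (movie, timeline)}``. With ``event_free=True`` the
    sampled schedule fixes only the movie length; no buds are rendered and the
    returned timelines are empty (negative-control movies).
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_cells)
    out: dict[str, tuple[np.ndarray, DivisionTimeline]] = {}
    for i in range(n_cells):
        cell_id = f"cell_{i:03d}"
        timeline = sample_division_schedule(params, int(seeds[2 * i]) % (2 ** 31))
        timeline = replace(timeline, cell_id=cell_id)
        if event_free:
            timeline = DivisionTimeline(cell_id=cell_id, event_frames=(),
                                        n_frames=timeline.n_frames)
        spec = replace(spec_template, cell_id=cell_id, rng_seed=int(seeds[2 * i + 1]) % (2 ** 31))
        movie, _ = render_cell_movie(spec, timeline, on_overlap=on_overlap)
        out[cell_id] = (movie, timeline)
    return out
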