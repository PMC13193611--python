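"""File formats and run configuration.

Movies are multi-page grayscale TIFFs (one page per frame); annotations and
tracking tables are headed CSVs with 0-based frame indices; checkpoints are
``.npz`` bundles carrying weights plus their full configuration and
normalization statistics, so inference is reproducible from the file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DivisionTimeline
from .detector import DetectorConfig
from .mae import MAEConfig
from .preprocess import NormStats

__all__ = [
    "read_movie",
    "write_movie",
    "read_annotations",
    "read_tracking",
    "save_checkpoint",
    "load_checkpoint",
    "RunConfig",
    "config_hash",
]

_CHECKPOINT_VERSION = 1


def read_movie(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF into a float (T, H, W) array in [0, 1].

    Page order is frame order. Integer dtypes are divided by their full
    range; the applied scale is recorded in the returned metadata.
    """
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: inconsistent page shapes {sorted(shapes)}")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
    else:
        scale = 1.0
    meta = {"path": str(path), "dtype": str(arr.dtype), "scale": scale,
            "n_frames": int(arr.shape[0])}
    return (arr.astype(np.float32) / scale), meta


def write_movie(path, movie: np.ndarray):
    """Write a float [0, 1] movie as a 16-bit multi-page TIFF."""
    movie = np.asarray(movie)
    tifffile.imwrite(path, (np.clip(movie, 0, 1) * 65535.0 + 0.5).astype(np.uint16),
                     photometric="minisblack")


def read_annotations(path, n_frames: dict[str, int] | None = None
                     ) -> dict[str, DivisionTimeline]:
    """Read a ``cell_id,event_frame`` CSV into per-cell timelines.

    Frames are grouped per cell, sorted and de-duplicated (duplicates raise a
    warning). ``n_frames`` optionally supplies movie lengths for validation.
    """
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "event_frame"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation CSV must have columns {sorted(required)}")
    if len(df) and not np.issubdtype(df["event_frame"].dtype, np.integer):
        as_float = df["event_frame"].astype(float)
        if not (as_float == as_float.round()).all():
            raise ValueError(f"{path}: event_frame values must be integers")
        df["event_frame"] = as_float.astype(int)
    out: dict[str, DivisionTimeline] = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        frames = sorted(grp["event_frame"].tolist())
        unique = sorted(set(frames))
        if len(unique) < len(frames):
            warnings.warn(f"{path}: duplicate event frames for cell {cell_id}; de-duplicated")
        nf = n_frames.get(str(cell_id)) if n_frames else None
        out[str(cell_id)] = DivisionTimeline(cell_id=str(cell_id),
                                             event_frames=tuple(unique), n_frames=nf)
    return out


def read_tracking(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "frame", "centroid_row", "centroid_col"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: tracking CSV must have columns {sorted(required)}")
    return df


def _config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg) if dataclasses.is_dataclass(cfg) else dict(cfg)


def save_checkpoint(path, state: dict[str, np.ndarray], *, mae_config: MAEConfig,
                    detector_config: DetectorConfig | None = None,
                    norm_stats: NormStats | None = None, extra: dict | None = None):
    """Write a self-describing ``.npz`` checkpoint (weights + configs)."""
    meta = {
        "version": _CHECKPOINT_VERSION,
        "mae_config": _config_to_dict(mae_config),
        "detector_config": _config_to_dict(detector_config) if detector_config else None,
        "norm_stats": dataclasses.asdict(norm_stats) if norm_stats else None,
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in state.items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    """Inverse of :func:`save_checkpoint`; returns (state, metadata) with
    ``metadata['mae_config']`` / ``['detector_config']`` rebuilt as dataclasses."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    if meta.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version {meta.get('version')}")
    meta["mae_config"] = MAEConfig(**meta["mae_config"])
    if meta.get("detector_config"):
        meta["detector_config"] = DetectorConfig(**meta["detector_config"])
    if meta.get("norm_stats"):
        meta["norm_stats"] = NormStats(**meta["norm_stats"])
    return state, meta


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs, serialized into every artifact."""

    seed: int = 0
    n_cells: int = 60
    train_frac: float = 2 / 3
    positive_span: int = 1
    frame_interval_min: float = 15.0
    tolerance: int = 1
    max_gap: int = 5
    sg_window: int = 11
    sg_polyorder: int = 2
    mae: MAEConfig = dataclasses.field(default_factory=lambda: MAEConfig(epochs=12))
    detector: DetectorConfig = dataclasses.field(
        default_factory=lambda: DetectorConfig(encoder_mode="frozen",
                                               frame_embedding="meanpool"))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "mae" in d:
            d["mae"] = MAEConfig(**d["mae"])
        if "detector" in d:
            d["detector"] = DetectorConfig(**d["detector"])
        return cls(**d)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:16]
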