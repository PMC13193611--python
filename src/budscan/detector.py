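"""Stage-2 division-event classifier.

Each frame of an 11-frame temporal stack is embedded by the pretrained
encoder with no patch masking (the class-token output summarizes the frame);
sinusoidal temporal embeddings encode the slot position; a lightweight
temporal transformer integrates the sequence and a two-way softmax head
emits the probability that a budding event occurs at the center frame.

Budding frames are rare, so training uses balanced mini-batches: every batch
holds equal numbers of budding and non-budding stacks, with the minority
class oversampled with replacement while each majority sample is visited at
least once per epoch. The encoder can be kept frozen (frame embeddings
computed once) or fine-tuned jointly at a reduced learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DivisionTimeline
from .mae import MAE, MAEConfig, MAEEncoder, patchify
from .nn import (AdamW, LayerNorm, Linear, Module, Tensor, TransformerBlock,
                 log_softmax, softmax)
from .preprocess import HALF_WINDOW, WINDOW, window_indices

__all__ = [
    "DetectorConfig",
    "FrameProbabilities",
    "TemporalHead",
    "Detector",
    "embed_frame",
    "embed_frames",
    "temporal_positional_table",
    "classify_stack",
    "balanced_batches",
    "train_detector",
    "predict_timeline",
    "DetectorLog",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Stage-2 hyperparameters.

    ``n_members`` temporal heads are trained from distinct initializations
    and batch streams and their softmax probabilities averaged at inference
    — a small deep ensemble that suppresses seed-specific single-frame
    hallucinations the individual heads produce in the small-data regime.
    With ``encoder_mode="finetune"`` the encoder is fine-tuned jointly with
    the first head (at ``encoder_lr_scale`` times the head learning rate);
    remaining members train frozen on the fine-tuned encoder.

    ``embedding_noise`` adds Gaussian noise to the frame embeddings during
    frozen-path training, expressed as a fraction of the per-dimension SD of
    the training embeddings — a regularizer that teaches the temporal head
    invariance to the embedding fluctuations pixel noise induces.
    """

    window: int = WINDOW
    temporal_depth: int = 2
    temporal_heads: int = 4
    temporal_dim: int = 128
    threshold: float = 0.5
    encoder_mode: str = "finetune"  # or "frozen"
    n_members: int = 5
    aggregate: str = "mean"  # or "median" across ensemble members
    frame_embedding: str = "cls"  # or "meanpool" over patch tokens
    embedding_noise: float = 0.0
    ignore_margin: int = 1
    lr: float = 1e-3
    encoder_lr_scale: float = 0.1
    epochs: int = 8
    batch_size: int = 32
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.window % 2 == 0:
            raise ValueError("window must be odd (a center frame is required)")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.encoder_mode not in ("frozen", "finetune"):
            raise ValueError("encoder_mode must be 'frozen' or 'finetune'")
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (balanced batches)")
        if self.temporal_dim % 2:
            raise ValueError("temporal_dim must be even (sinusoidal table)")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.embedding_noise < 0:
            raise ValueError("embedding_noise must be >= 0")
        if self.ignore_margin < 0:
            raise ValueError("ignore_margin must be >= 0")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")
        if self.frame_embedding not in ("cls", "meanpool"):
            raise ValueError("frame_embedding must be 'cls' or 'meanpool'")


@dataclass(frozen=True)
class FrameProbabilities:
    """Per-frame budding probabilities over a whole movie."""

    cell_id: str
    probs: np.ndarray  # (T,)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 1 or ((p < 0) | (p > 1)).any():
            raise ValueError("probs must be a 1-D array of values in [0, 1]")
        object.__setattr__(self, "probs", p)


def temporal_positional_table(T: int, d: int) -> np.ndarray:
    """Standard sinusoidal position table, shape (T, d):
    ``table[t, 2i] = sin(t / 10000^(2i/d))``, ``table[t, 2i+1]`` the cosine."""
    if d % 2:
        raise ValueError("embedding dimension must be even")
    t = np.arange(T)[:, None]
    i = np.arange(d // 2)[None, :]
    angle = t / np.power(10000.0, 2 * i / d)
    table = np.empty((T, d), dtype=np.float64)
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return table


def embed_frame(encoder: MAEEncoder, crop: np.ndarray) -> np.ndarray:
    """Class-token embedding of one normalized crop (no masking)."""
    return embed_frames(encoder, np.asarray(crop)[None])[0]


def embed_frames(encoder: MAEEncoder, crops: np.ndarray, batch: int = 64,
                 mode: str = "cls") -> np.ndarray:
    """Embed (N, H, W) normalized crops -> (N, encoder_dim), full visibility.

    ``mode="cls"`` takes the class-token output (meaningful once the encoder
    is fine-tuned for classification); ``mode="meanpool"`` averages the
    patch-token outputs — the standard protocol for probing a *frozen*
    masked-auto-encoder, whose pretraining gives the class token no explicit
    summarization objective.
    """
    if mode not in ("cls", "meanpool"):
        raise ValueError("mode must be 'cls' or 'meanpool'")
    out = []
    p = encoder.cfg.patch_size
    for lo in range(0, len(crops), batch):
        patches = patchify(np.asarray(crops[lo:lo + batch], dtype=np.float32), p)
        tok = encoder(patches).data
        out.append(tok[:, 0, :] if mode == "cls" else tok[:, 1:, :].mean(axis=1))
    return np.concatenate(out, axis=0)


class TemporalHead(Module):
    """Temporal transformer over 11 frame embeddings + 2-way softmax head.

    The prediction attaches to the center frame: the center slot's output
    token feeds the classification head.
    """

    def __init__(self, cfg: DetectorConfig, encoder_dim: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.in_proj = Linear(encoder_dim, cfg.temporal_dim, rng)
        self.blocks = [TransformerBlock(cfg.temporal_dim, cfg.temporal_heads, rng)
                       for _ in range(cfg.temporal_depth)]
        self.norm = LayerNorm(cfg.temporal_dim)
        self.head = Linear(cfg.temporal_dim, 2, rng)
        self.pos_table = temporal_positional_table(cfg.window, cfg.temporal_dim).astype(np.float32)

    def __call__(self, frame_embeddings: Tensor) -> Tensor:
        """(B, window, encoder_dim) -> logits (B, 2): (non-budding, budding)."""
        if frame_embeddings.shape[1] != self.cfg.window:
            raise ValueError(f"expected {self.cfg.window} frames, got {frame_embeddings.shape[1]}")
        x = self.in_proj(frame_embeddings) + Tensor(self.pos_table[None])
        for blk in self.blocks:
            x = blk(x)
        center = self.cfg.window // 2
        return self.head(self.norm(x)[:, center, :])



class Detector(Module):
    """Encoder plus an ensemble of temporal heads.

    Inference averages the members' softmax probabilities; training
    addresses one member at a time via the ``member`` arguments.
    """

    def __init__(self, mae_cfg: MAEConfig, det_cfg: DetectorConfig, seed: int | None = None):
        super().__init__()
        rng = np.random.default_rng(det_cfg.seed if seed is None else seed)
        self.mae_cfg = mae_cfg
        self.det_cfg = det_cfg
        self.encoder = MAEEncoder(mae_cfg, rng)
        self.heads = [TemporalHead(det_cfg, mae_cfg.encoder_dim, rng)
                      for _ in range(det_cfg.n_members)]

    def logits_from_embeddings(self, emb: np.ndarray | Tensor, member: int = 0) -> Tensor:
        e = emb if isinstance(emb, Tensor) else Tensor(np.asarray(emb, dtype=np.float32))
        return self.heads[member](e)

    def logits_from_crops(self, crops: np.ndarray, member: int = 0) -> Tensor:
        """(B, window, H, W) -> logits, keeping the encoder in the graph
        (fine-tuning path)."""
        B, W = crops.shape[0], crops.shape[1]
        flat = crops.reshape(B * W, *crops.shape[2:])
        tokens = self.encoder(patchify(flat.astype(np.float32), self.mae_cfg.patch_size))
        if self.det_cfg.frame_embedding == "cls":
            frame = tokens[:, 0, :]
        else:
            frame = tokens[:, 1:, :].mean(axis=1)
        return self.heads[member](frame.reshape(B, W, self.mae_cfg.encoder_dim))

    def probs_from_embeddings(self, emb: np.ndarray) -> np.ndarray:
        """Ensemble-aggregated (B, 2) probabilities (mean or median over
        members per the config; the median is renormalized to sum to 1)."""
        e = Tensor(np.asarray(emb, dtype=np.float32))
        probs = np.stack([softmax(h(e)).data for h in self.heads])
        if self.det_cfg.aggregate == "median":
            agg = np.median(probs, axis=0)
            return agg / agg.sum(axis=-1, keepdims=True)
        return probs.mean(axis=0)


def classify_stack(detector: Detector, embeddings: np.ndarray) -> np.ndarray:
    """Probability pair (non-budding, budding) for one 11-frame stack of
    frame embeddings (window, encoder_dim), averaged over ensemble members."""
    return detector.probs_from_embeddings(np.asarray(embeddings)[None])[0]


def balanced_batches(labels: np.ndarray, batch_size: int, seed: int):
    """Yield index batches with exactly ``batch_size/2`` of each class.

    The majority class is shuffled and chunked so every sample is visited at
    least once per epoch; the minority class is oversampled with replacement
    (reshuffled cycling) to fill its half of each batch. The final partial
    majority chunk is topped up with replacement.
    """
    labels = np.asarray(labels)
    if batch_size % 2:
        raise ValueError("batch_size must be even")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for balanced batching")
    rng = np.random.default_rng(seed)
    major, minor = (neg, pos) if len(neg) >= len(pos) else (pos, neg)
    half = batch_size // 2
    major_order = rng.permutation(major)
    minor_pool = rng.permutation(minor)
    mi = 0
    for lo in range(0, len(major_order), half):
        maj = major_order[lo:lo + half]
        if len(maj) < half:
            maj = np.concatenate([maj, rng.choice(major, half - len(maj), replace=True)])
        mins = []
        while len(mins) < half:
            if mi >= len(minor_pool):
                minor_pool = rng.permutation(minor)
                mi = 0
            take = min(half - len(mins), len(minor_pool) - mi)
            mins.extend(minor_pool[mi:mi + take])
            mi += take
        batch = np.concatenate([maj, np.asarray(mins)])
        yield rng.permutation(batch)


@dataclass
class DetectorLog:
    train_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    encoder_mode: str = "frozen"

    @property
    def best_checkpoint(self) -> int:
        return int(np.argmax(self.val_f1))


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    lp = log_softmax(logits)
    onehot = np.zeros((len(labels), 2), dtype=np.float32)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(lp * Tensor(onehot)).sum() * (1.0 / len(labels))


def _window_embedding_batch(emb: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Gather 11-frame windows (with edge replication) from per-frame
    embeddings (T, D) at the given center frames."""
    T = emb.shape[0]
    idx = np.clip(centers[:, None] + np.arange(-HALF_WINDOW, HALF_WINDOW + 1)[None, :], 0, T - 1)
    return emb[idx]


def predict_timeline(detector: Detector, movie: np.ndarray,
                     cell_id: str = "", frame_embeddings: np.ndarray | None = None,
                     batch: int = 256, member: int | None = None) -> FrameProbabilities:
    """Budding probability for every frame of a normalized movie via sliding
    11-frame windows with boundary replication identical to training.

    Probabilities are averaged over the ensemble members; ``member`` selects
    a single head instead (used during per-member model selection)."""
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] < 1:
        raise ValueError("movie must be a non-empty (T, H, W) array")
    emb = (frame_embeddings if frame_embeddings is not None
           else embed_frames(detector.encoder, movie,
                             mode=detector.det_cfg.frame_embedding))
    T = emb.shape[0]
    probs = np.empty(T, dtype=np.float64)
    for lo in range(0, T, batch):
        centers = np.arange(lo, min(lo + batch, T))
        windows = _window_embedding_batch(emb, centers)
        if member is None:
            probs[centers] = detector.probs_from_embeddings(windows)[:, 1]
        else:
            logits = detector.logits_from_embeddings(windows, member=member)
            probs[centers] = softmax(logits).data[:, 1]
    return FrameProbabilities(cell_id=cell_id, probs=probs)


def train_detector(train_data: dict[str, tuple[np.ndarray, np.ndarray]],
                   val_data: dict[str, tuple[np.ndarray, DivisionTimeline]],
                   encoder_state: dict[str, np.ndarray],
                   mae_cfg: MAEConfig, cfg: DetectorConfig,
                   verbose: bool = False,
                   train_embeddings: dict[str, np.ndarray] | None = None,
                   val_embeddings: dict[str, np.ndarray] | None = None
                   ) -> tuple[Detector, DetectorLog]:
    """Train the temporal-head ensemble (optionally fine-tuning the encoder).

    ``train_data``: ``{cell_id: (normalized movie (T,H,W), labels (T,))}``;
    ``val_data``: ``{cell_id: (normalized movie, ground-truth timeline)}``
    from cells disjoint with training. Each member's checkpoint with the
    best validation F1 at +/-1-frame tolerance is retained. Precomputed
    frame embeddings may be supplied to skip the frozen-path embedding pass.
    """
    from .evaluate import detection_scores, match_events
    from .postprocess import binarize, collapse_runs

    if set(train_data) & set(val_data):
        raise ValueError("train and validation cells must be disjoint")
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, batch_seed = (int(s) % (2 ** 31) for s in ss.generate_state(2))
    detector = Detector(mae_cfg, cfg, seed=init_seed)
    detector.encoder.load_state_dict(encoder_state)

    cells = sorted(train_data)
    cell_of, center_of, labels = [], [], []
    for ci, c in enumerate(cells):
        _, lab = train_data[c]
        lab = np.asarray(lab, dtype=int)
        keep = np.ones(len(lab), dtype=bool)
        if cfg.ignore_margin > 0:
            # frames adjacent to a positive are near-duplicates of the event
            # and are excluded from the negative pool (ambiguity zone)
            for t in np.flatnonzero(lab == 1):
                lo = max(0, t - cfg.ignore_margin)
                hi = min(len(lab), t + cfg.ignore_margin + 1)
                keep[lo:hi] = lab[lo:hi] == 1
        idx = np.flatnonzero(keep)
        cell_of += [ci] * len(idx)
        center_of += idx.tolist()
        labels += lab[idx].tolist()
    cell_of = np.asarray(cell_of)
    center_of = np.asarray(center_of)
    labels = np.asarray(labels, dtype=int)

    def _embed_caches(reuse: bool):
        if reuse and train_embeddings is not None and val_embeddings is not None:
            return dict(train_embeddings), dict(val_embeddings)
        emb_cache = {c: embed_frames(detector.encoder, movie, mode=cfg.frame_embedding)
                     for c, (movie, _) in train_data.items()}
        val_emb = {c: embed_frames(detector.encoder, movie, mode=cfg.frame_embedding)
                   for c, (movie, _) in val_data.items()}
        return emb_cache, val_emb

    def _val_f1(member: int, val_emb) -> float:
        tp = fp = fn = 0
        for c, (movie, truth) in val_data.items():
            emb = val_emb[c] if val_emb is not None else None
            fp_probs = predict_timeline(detector, movie, cell_id=c,
                                        frame_embeddings=emb, member=member)
            pred = collapse_runs(binarize(fp_probs, cfg.threshold))
            sc = detection_scores(match_events(truth, pred, max_gap=5), tolerance=1)
            tp += sc.tp
            fp += sc.fp
            fn += sc.fn
        return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    def _train_member(member: int, finetune_encoder: bool, emb_cache, val_emb,
                      noise_scale=None):
        head = detector.heads[member]
        noise_rng = np.random.default_rng(batch_seed + 7919 * member + 13)
        if finetune_encoder:
            params = {**{f"encoder.{k}": v for k, v in detector.encoder.parameters().items()},
                      **{f"head.{k}": v for k, v in head.parameters().items()}}
            lr_scales = {"encoder.": cfg.encoder_lr_scale}
        else:
            params = head.parameters()
            lr_scales = None
        opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay, lr_scales=lr_scales)
        if not finetune_encoder:
            # flat view of all cached embeddings + per-sample window indices,
            # so batch assembly is a single fancy-index gather
            flat_emb = np.concatenate([emb_cache[c] for c in cells])
            offsets = np.cumsum([0] + [len(emb_cache[c]) for c in cells[:-1]])
            lengths = np.asarray([len(emb_cache[c]) for c in cells])
            rel = np.arange(-HALF_WINDOW, HALF_WINDOW + 1)
            win_idx = (offsets[cell_of][:, None]
                       + np.clip(center_of[:, None] + rel[None, :], 0,
                                 (lengths[cell_of] - 1)[:, None])).astype(np.int64)
        best_f1, best_state = -1.0, None
        for epoch in range(cfg.epochs):
            # cosine decay of the head lr across epochs
            lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
            epoch_loss, n_batches = 0.0, 0
            for batch_idx in balanced_batches(labels, cfg.batch_size,
                                              seed=batch_seed + 997 * member + epoch):
                y = labels[batch_idx]
                if finetune_encoder:
                    crops = np.stack([
                        train_data[cells[cell_of[i]]][0][
                            np.clip(np.arange(center_of[i] - HALF_WINDOW,
                                              center_of[i] + HALF_WINDOW + 1), 0,
                                    len(train_data[cells[cell_of[i]]][0]) - 1)]
                        for i in batch_idx])
                    logits = detector.logits_from_crops(crops, member=member)
                else:
                    emb = flat_emb[win_idx[batch_idx]]
                    if noise_scale is not None:
                        emb = emb + noise_scale * noise_rng.standard_normal(
                            emb.shape).astype(np.float32)
                    logits = detector.logits_from_embeddings(emb, member=member)
                loss = _cross_entropy(logits, y)
                lv = loss.data.item()
                if not np.isfinite(lv):
                    raise RuntimeError(f"non-finite detector loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step(lr=lr)
                epoch_loss += lv
                n_batches += 1
            log.train_loss.append(epoch_loss / max(n_batches, 1))
            f1 = _val_f1(member, val_emb)
            log.val_f1.append(f1)
            if verbose:
                print(f"member {member} epoch {epoch}: loss {log.train_loss[-1]:.4f} "
                      f"val F1(+/-1) {f1:.3f}")
            if f1 > best_f1:
                best_f1 = f1
                best_state = {k: v.copy() for k, v in head.state_dict().items()}
                if finetune_encoder:
                    best_state_enc = {k: v.copy()
                                      for k, v in detector.encoder.state_dict().items()}
        if best_state is not None:
            head.load_state_dict(best_state)
            if finetune_encoder:
                detector.encoder.load_state_dict(best_state_enc)

    def _noise_scale(emb_cache):
        if cfg.embedding_noise == 0:
            return None
        allemb = np.concatenate(list(emb_cache.values()))
        return (cfg.embedding_noise * allemb.std(axis=0)).astype(np.float32)

    log = DetectorLog(encoder_mode=cfg.encoder_mode)
    if cfg.encoder_mode == "finetune":
        # member 0 fine-tunes the encoder; remaining members train frozen on
        # the fine-tuned embeddings
        _train_member(0, True, None, None)
        emb_cache, val_emb = _embed_caches(reuse=False)
        scale = _noise_scale(emb_cache)
        for m in range(1, cfg.n_members):
            _train_member(m, False, emb_cache, val_emb, noise_scale=scale)
    else:
        emb_cache, val_emb = _embed_caches(reuse=True)
        scale = _noise_scale(emb_cache)
        for m in range(cfg.n_members):
            _train_member(m, False, emb_cache, val_emb, noise_scale=scale)
    return detector, log
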