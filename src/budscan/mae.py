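"""Masked auto-encoder pretraining for single-cell crops.

Stage 1 of the two-stage detection framework. Each 64 x 64 crop is split
into non-overlapping patches; a large random fraction of patches is hidden
and only the visible ones (plus a class token) pass through a vision
transformer encoder. A small decoder receives the encoded visible tokens
together with a learnable mask token inserted at every hidden position,
unshuffles the sequence back to the original patch order via the stored
permutation, and reconstructs the image. Training minimizes the mean squared
reconstruction error (by default on masked patches only) and uses the full
stabilization recipe: AdamW, linear warmup followed by cosine annealing with
periodic restarts, gradient accumulation, an exponential-moving-average
weight copy, and checkpoint selection by validation loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (AdamW, Linear, Module, Tensor, TransformerBlock, broadcast_to,
                 concat, gather_tokens)

__all__ = [
    "MAEConfig",
    "MaskPlan",
    "TrainingLog",
    "MAEEncoder",
    "MAE",
    "patchify",
    "unpatchify",
    "random_masking",
    "restore_sequence",
    "reconstruction_loss",
    "ema_update",
    "lr_at",
    "pretrain",
    "masked_mse",
    "mean_baseline_mse",
]


@dataclass(frozen=True)
class MAEConfig:
    """Hyperparameters of the masked auto-encoder and its training loop.

    Defaults are a "tiny" configuration sized for 64 x 64 crops: an 8 px
    patch gives an 8 x 8 token grid, the encoder is dim 128 / depth 4 and the
    decoder dim 64 / depth 2. ``mask_ratio`` 0.75 follows the canonical
    masked-auto-encoder recipe. ``loss_on`` selects whether the
    reconstruction loss is computed on masked patches only (canonical) or on
    all patches.
    """

    patch_size: int = 8
    image_size: int = 64
    encoder_dim: int = 128
    encoder_depth: int = 4
    encoder_heads: int = 4
    decoder_dim: int = 64
    decoder_depth: int = 2
    decoder_heads: int = 4
    mask_ratio: float = 0.75
    base_lr: float = 1.5e-3
    warmup_steps: int = 40
    cycle_steps: int = 200
    min_lr: float = 1e-5
    ema_decay: float = 0.999
    grad_accum_steps: int = 1
    weight_decay: float = 0.01
    epochs: int = 30
    batch_size: int = 64
    loss_on: str = "masked"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.mask_ratio < 1):
            raise ValueError("mask_ratio must be in [0, 1)")
        if not (0 <= self.ema_decay <= 1):
            raise ValueError("ema_decay must be in [0, 1]")
        if self.loss_on not in ("masked", "all"):
            raise ValueError("loss_on must be 'masked' or 'all'")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        for name in ("patch_size", "encoder_dim", "encoder_depth", "encoder_heads",
                     "decoder_dim", "decoder_depth", "decoder_heads", "grad_accum_steps",
                     "epochs", "batch_size", "warmup_steps", "cycle_steps"):
            if getattr(self, name) <= 0 and name != "warmup_steps":
                raise ValueError(f"{name} must be positive")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2


@dataclass(frozen=True)
class MaskPlan:
    """Which patches of each image are masked, and how to restore order.

    ``shuffle_perm`` (B, P) is a per-image permutation whose first
    ``n_visible`` entries are the visible patch indices; ``restore_indices``
    is its inverse, so gathering a shuffled sequence by ``restore_indices``
    returns original patch order.
    """

    mask_ratio: float
    shuffle_perm: np.ndarray  # (B, P) int
    n_visible: int

    @property
    def restore_indices(self) -> np.ndarray:
        return np.argsort(self.shuffle_perm, axis=1)

    @property
    def visible_indices(self) -> np.ndarray:
        return self.shuffle_perm[:, :self.n_visible]

    def mask_bool(self) -> np.ndarray:
        """(B, P) boolean, True where the patch is masked."""
        B, P = self.shuffle_perm.shape
        m = np.ones((B, P), dtype=bool)
        np.put_along_axis(m, self.visible_indices, False, axis=1)
        return m


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    ema_val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def best_checkpoint(self) -> int:
        return int(np.argmin(self.val_loss))


def patchify(images: np.ndarray, p: int) -> np.ndarray:
    """(B, H, W) -> (B, P, p*p) in row-major patch order (also accepts a
    single (H, W) image, returning (P, p*p))."""
    single = images.ndim == 2
    x = images[None] if single else images
    B, H, W = x.shape
    if H % p or W % p:
        raise ValueError(f"image dims {(H, W)} not divisible by patch size {p}")
    gh, gw = H // p, W // p
    out = (x.reshape(B, gh, p, gw, p).transpose(0, 1, 3, 2, 4).reshape(B, gh * gw, p * p))
    return out[0] if single else out


def unpatchify(patches: np.ndarray, p: int, image_size: int) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    single = patches.ndim == 2
    x = patches[None] if single else patches
    g = image_size // p
    B = x.shape[0]
    out = x.reshape(B, g, g, p, p).transpose(0, 1, 3, 2, 4).reshape(B, image_size, image_size)
    return out[0] if single else out


def random_masking(n_patches: int, mask_ratio: float, rng: np.random.Generator,
                   batch: int = 1) -> MaskPlan:
    """Draw a uniform random mask plan: exactly
    ``P - floor(mask_ratio * P)`` patches stay visible in every image."""
    if not (0 <= mask_ratio < 1):
        raise ValueError("mask_ratio must be in [0, 1)")
    n_visible = n_patches - int(math.floor(mask_ratio * n_patches))
    perms = np.stack([rng.permutation(n_patches) for _ in range(batch)])
    return MaskPlan(mask_ratio=mask_ratio, shuffle_perm=perms, n_visible=n_visible)


class MAEEncoder(Module):
    """Vision-transformer encoder with a class token and learnable
    positional embeddings, applied to visible patches only (or to all
    patches when no plan is given, as in downstream inference)."""

    def __init__(self, cfg: MAEConfig, rng: np.random.Generator):
        super().__init__()
        P, D = cfg.n_patches, cfg.encoder_dim
        self.cfg = cfg
        self.patch_embed = Linear(cfg.patch_size ** 2, D, rng)
        self.pos_embed = Tensor((rng.standard_normal((1, P + 1, D)) * 0.02).astype(np.float32),
                                requires_grad=True)
        self.cls_token = Tensor((rng.standard_normal((1, 1, D)) * 0.02).astype(np.float32),
                                requires_grad=True)
        self.blocks = [TransformerBlock(D, cfg.encoder_heads, rng) for _ in range(cfg.encoder_depth)]
        from .nn import LayerNorm
        self.norm = LayerNorm(D)

    def __call__(self, patches: np.ndarray, plan: MaskPlan | None = None) -> Tensor:
        """``patches``: (B, P, p*p) numpy. Returns (B, 1 + K, D) tokens where
        slot 0 is the class token and K is the number of (visible) patches."""
        B = patches.shape[0]
        # positional embedding added by ORIGINAL patch position, before any
        # shuffling, so masked training and full inference agree
        tok = self.patch_embed(Tensor(patches.astype(np.float32))) + self.pos_embed[:, 1:, :]
        if plan is not None:
            if plan.shuffle_perm.shape[1] != self.cfg.n_patches:
                raise ValueError("mask plan inconsistent with patch grid")
            tok = gather_tokens(tok, plan.visible_indices)
        cls = broadcast_to(self.cls_token + self.pos_embed[:, :1, :],
                           (B, 1, self.cfg.encoder_dim))
        x = concat([cls, tok], axis=1)
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)


def restore_sequence(visible: Tensor, mask_token: Tensor, plan: MaskPlan) -> Tensor:
    """Insert mask tokens at masked positions and unshuffle to original order.

    ``visible``: (B, K, D) tokens in shuffled (visible-first) order. Returns
    (B, P, D) with every visible token at its original grid index and the
    mask token at every masked index.
    """
    B, K, D = visible.shape
    if K != plan.n_visible:
        raise ValueError(f"got {K} visible tokens but plan expects {plan.n_visible}")
    P = plan.shuffle_perm.shape[1]
    masked = broadcast_to(mask_token, (B, P - K, D))
    full = concat([visible, masked], axis=1)  # still in shuffled order
    return gather_tokens(full, plan.restore_indices)


class MAEDecoder(Module):
    def __init__(self, cfg: MAEConfig, rng: np.random.Generator):
        super().__init__()
        P, D = cfg.n_patches, cfg.decoder_dim
        self.cfg = cfg
        self.embed = Linear(cfg.encoder_dim, D, rng)
        self.mask_token = Tensor((rng.standard_normal((1, 1, D)) * 0.02).astype(np.float32),
                                 requires_grad=True)
        self.pos_embed = Tensor((rng.standard_normal((1, P + 1, D)) * 0.02).astype(np.float32),
                                requires_grad=True)
        self.blocks = [TransformerBlock(D, cfg.decoder_heads, rng) for _ in range(cfg.decoder_depth)]
        from .nn import LayerNorm
        self.norm = LayerNorm(D)
        self.head = Linear(D, cfg.patch_size ** 2, rng)

    def __call__(self, latents: Tensor, plan: MaskPlan) -> Tensor:
        """``latents``: (B, 1 + K, D_enc) encoder output. Returns predicted
        patches (B, P, p*p) in original order."""
        x = self.embed(latents)
        cls, vis = x[:, :1, :], x[:, 1:, :]
        full = restore_sequence(vis, self.mask_token, plan)
        full = full + self.pos_embed[:, 1:, :]
        x = concat([cls + self.pos_embed[:, :1, :], full], axis=1)
        for blk in self.blocks:
            x = blk(x)
        return self.head(self.norm(x))[:, 1:, :]


class MAE(Module):
    def __init__(self, cfg: MAEConfig, seed: int | None = None):
        super().__init__()
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        self.cfg = cfg
        self.encoder = MAEEncoder(cfg, rng)
        self.decoder = MAEDecoder(cfg, rng)

    def loss(self, images: np.ndarray, plan: MaskPlan) -> Tensor:
        """Scalar reconstruction loss for a batch of (B, H, W) images."""
        p = self.cfg.patch_size
        patches = patchify(images, p)
        latents = self.encoder(patches, plan)
        pred = self.decoder(latents, plan)
        diff = pred - Tensor(patches.astype(np.float32))
        sq = diff * diff
        if self.cfg.loss_on == "all":
            return sq.mean()
        mask = plan.mask_bool()[:, :, None].astype(np.float32)
        denom = float(mask.sum() * p * p)
        if denom == 0:
            return sq.mean() * 0.0
        return (sq * Tensor(mask)).sum() * (1.0 / denom)

    def reconstruct(self, images: np.ndarray, plan: MaskPlan) -> np.ndarray:
        """Reconstructed images (B, H, W), numpy (no gradients kept)."""
        p = self.cfg.patch_size
        pred = self.decoder(self.encoder(patchify(images, p), plan), plan)
        return unpatchify(pred.data, p, self.cfg.image_size)


def reconstruction_loss(pred: np.ndarray, target: np.ndarray, plan: MaskPlan,
                        patch_size: int, loss_on: str = "masked") -> float:
    """Mean squared pixel error between two images (or batches), computed on
    masked patches only under the canonical convention (``loss_on='all'``
    averages over every pixel)."""
    pred, target = np.asarray(pred, dtype=np.float64), np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    pp = patchify(pred, patch_size)
    tp = patchify(target, patch_size)
    if pp.ndim == 2:
        pp, tp = pp[None], tp[None]
    sq = (pp - tp) ** 2
    if loss_on == "all":
        return float(sq.mean())
    mask = plan.mask_bool()
    if mask.sum() == 0:
        return 0.0
    return float(sq[mask].mean())


def ema_update(ema_state: dict[str, np.ndarray], current: dict[str, np.ndarray],
               decay: float) -> dict[str, np.ndarray]:
    """In-place exponential moving average: ``ema <- decay*ema + (1-decay)*w``."""
    if not (0 <= decay <= 1):
        raise ValueError("decay must be in [0, 1]")
    for k, w in current.items():
        e = ema_state[k]
        if e.shape != w.shape:
            raise ValueError(f"shape mismatch for {k}")
        e *= decay
        e += (1.0 - decay) * w
    return ema_state


def lr_at(step: int, cfg: MAEConfig) -> float:
    """Warmup + cosine annealing with periodic restarts.

    Linear ramp 0 -> base_lr over ``warmup_steps``; afterwards
    ``min_lr + 0.5*(base_lr - min_lr)*(1 + cos(pi * t_c / cycle_steps))``
    where ``t_c`` resets every ``cycle_steps`` (so each restart boundary
    returns to ``base_lr``).
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if cfg.warmup_steps > 0 and step < cfg.warmup_steps:
        return cfg.base_lr * step / cfg.warmup_steps
    t_c = (step - cfg.warmup_steps) % cfg.cycle_steps
    return cfg.min_lr + 0.5 * (cfg.base_lr - cfg.min_lr) * (1 + math.cos(math.pi * t_c / cfg.cycle_steps))


def _eval_loss(model: MAE, images: np.ndarray, plans: list[MaskPlan],
               batch: int = 256) -> float:
    total, n = 0.0, 0
    for (lo, plan) in plans:
        chunk = images[lo:lo + plan.shuffle_perm.shape[0]]
        total += model.loss(chunk, plan).data.item() * chunk.shape[0]
        n += chunk.shape[0]
    return total / max(n, 1)


def _fixed_plans(n_images: int, cfg: MAEConfig, seed: int, batch: int = 64):
    """Deterministic masking plans for a validation set, reused every epoch so
    validation losses are comparable across epochs."""
    rng = np.random.default_rng(seed)
    plans = []
    for lo in range(0, n_images, batch):
        b = min(batch, n_images - lo)
        plans.append((lo, random_masking(cfg.n_patches, cfg.mask_ratio, rng, batch=b)))
    return plans


def masked_mse(model: MAE, images: np.ndarray, plans) -> float:
    """Held-out masked-patch reconstruction MSE under fixed plans."""
    return _eval_loss(model, images, plans)


def mean_baseline_mse(images: np.ndarray, cfg: MAEConfig, plans) -> float:
    """MSE of predicting every masked pixel by the mean of the image's
    visible patches — the no-learning reference the trained model must beat."""
    total, n = 0.0, 0
    for lo, plan in plans:
        chunk = patchify(images[lo:lo + plan.shuffle_perm.shape[0]], cfg.patch_size)
        vis = np.take_along_axis(chunk, plan.visible_indices[:, :, None], axis=1)
        mean = vis.mean(axis=(1, 2), keepdims=True)
        mask = plan.mask_bool()
        sq = (chunk - mean) ** 2
        total += sq[mask].sum() / chunk.shape[2]
        n += mask.sum()
    return float(total / max(n, 1))


def pretrain(train_images: np.ndarray, val_images: np.ndarray, cfg: MAEConfig,
             verbose: bool = False) -> tuple[MAE, dict[str, np.ndarray], TrainingLog]:
    """Pretrain a masked auto-encoder.

    ``train_images`` / ``val_images``: (N, H, W) normalized crops from
    disjoint cell sets. Returns the model loaded with the best-validation
    checkpoint, the EMA weight copy, and the training log. Gradients are
    accumulated over ``grad_accum_steps`` micro-batches (loss scaled per
    micro-batch) before each optimizer update. Raises on NaN loss.
    """
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation sets must be non-empty")
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, shuffle_seed, mask_seed, val_seed = (int(s) % (2 ** 31) for s in ss.generate_state(4))
    model = MAE(cfg, seed=init_seed)
    params = model.parameters()
    opt = AdamW(params, lr=0.0, weight_decay=cfg.weight_decay)
    ema_state = {k: v.copy() for k, v in model.state_dict().items()}
    log = TrainingLog()
    val_plans = _fixed_plans(len(val_images), cfg, val_seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    mask_rng = np.random.default_rng(mask_seed)

    best_state, best_val = None, np.inf
    opt_step = 0
    micro = 0
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(train_images))
        epoch_loss, n_batches = 0.0, 0
        opt.zero_grad()
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            plan = random_masking(cfg.n_patches, cfg.mask_ratio, mask_rng, batch=len(idx))
            loss = model.loss(train_images[idx], plan)
            val = loss.data.item()
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {val}")
            epoch_loss += val
            n_batches += 1
            (loss * (1.0 / cfg.grad_accum_steps)).backward()
            micro += 1
            if micro % cfg.grad_accum_steps == 0:
                lr = lr_at(opt_step, cfg)
                opt.step(lr=lr)
                opt.zero_grad()
                ema_update(ema_state, {k: p.data for k, p in params.items()}, cfg.ema_decay)
                opt_step += 1
        log.train_loss.append(epoch_loss / max(n_batches, 1))
        log.lr.append(lr_at(max(opt_step - 1, 0), cfg))
        v = _eval_loss(model, val_images, val_plans)
        log.val_loss.append(v)
        raw_state = model.state_dict()
        model.load_state_dict(ema_state)
        log.ema_val_loss.append(_eval_loss(model, val_images, val_plans))
        model.load_state_dict(raw_state)
        if v < best_val:
            best_val, best_state = v, raw_state
        if verbose:
            print(f"epoch {epoch}: train {log.train_loss[-1]:.4f} val {v:.4f}")
    model.load_state_dict(best_state)
    return model, ema_state, log
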