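"""Adam with decoupled weight decay, with per-group learning-rate scales."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Adam optimizer with decoupled weight decay.

    ``groups`` maps a group name to ``(params, lr_scale)`` where ``params`` is
    a name->Tensor dict; 1-D parameters (biases, layer-norm gains) are exempt
    from weight decay, following common transformer practice.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 lr_scales: dict[str, float] | None = None):
        self.params = dict(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.lr_scales = lr_scales or {}
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def _scale_for(self, name: str) -> float:
        for prefix, s in self.lr_scales.items():
            if name.startswith(prefix):
                return s
        return 1.0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None):
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            lr_k = self.lr * self._scale_for(k)
            m = self._m[k]
            v = self._v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                update = update + self.weight_decay * p.data
            p.data -= (lr_k * update).astype(p.data.dtype)
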