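"""Transformer building blocks on the autograd core.

Pre-norm transformer blocks with multi-head self-attention and GELU MLPs,
the configuration used by both the masked-auto-encoder stages and the
temporal classification head. Weight init follows the usual vision
transformer recipe (truncated-normal-like std 0.02 for projections).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadAttention",
    "TransformerBlock",
    "gelu",
    "softmax",
    "log_softmax",
]


class Module:
    """Lightweight container tracking parameters and submodules by attribute."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for mname, mod in self._modules.items():
            for pname, p in mod.parameters().items():
                out[f"{mname}.{pname}"] = p
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            if state[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {state[k].shape} vs {p.data.shape}")
            p.data = state[k].astype(p.data.dtype, copy=True)


def _param(rng: np.random.Generator, shape, std: float = 0.02, dtype=np.float32) -> Tensor:
    return Tensor((rng.standard_normal(shape) * std).astype(dtype), requires_grad=True)


def _zeros(shape, dtype=np.float32) -> Tensor:
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = _param(rng, (in_dim, out_dim), std=in_dim ** -0.5, dtype=dtype)
        self.bias = _zeros((out_dim,), dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.bias = _zeros((dim,), dtype=dtype)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        # fused layer-norm primitive (single graph node per call)
        w, b, eps = self.weight, self.bias, self.eps
        xd = x.data
        mu = xd.mean(axis=-1, keepdims=True)
        xc = xd - mu
        inv = 1.0 / np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + eps)
        xhat = xc * inv
        out_data = xhat * w.data + b.data

        def backward(g):
            if w.requires_grad:
                axes = tuple(range(g.ndim - 1))
                w._accumulate((g * xhat).sum(axis=axes))
                b._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                dxhat = g * w.data
                m1 = dxhat.mean(axis=-1, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
                x._accumulate(inv * (dxhat - m1 - xhat * m2))

        return x._make(out_data, (x, w, b), backward)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation), fused fwd/bwd.

    Written with in-place temporaries: these arrays are large (batch x
    tokens x mlp-hidden) and allocation churn dominates otherwise.
    """
    xd = x.data
    u = xd * xd
    u *= xd
    u *= 0.044715
    u += xd
    u *= _GELU_C
    t = np.tanh(u, out=u)
    out_data = t + 1.0
    out_data *= xd
    out_data *= 0.5

    def backward(g):
        if x.requires_grad:
            du = xd * xd
            du *= 3 * 0.044715
            du += 1.0
            du *= _GELU_C
            du *= 1.0 - t * t
            du *= xd
            du += 1.0 + t
            du *= 0.5
            du *= g
            x._accumulate(du)

    return x._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return x._make(s, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - np.exp(out_data) * g.sum(axis=axis, keepdims=True))

    return x._make(out_data, (x,), backward)


class MultiHeadAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng, dtype=dtype)
        self.proj = Linear(dim, dim, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(B, T, 3, h, hd).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (B, h, T, hd)
        attn = softmax((q @ k.transpose((0, 1, 3, 2))) * (hd ** -0.5), axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm block: x + MHA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0, dtype=np.float32):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim, dtype=dtype)
        self.attn = MultiHeadAttention(dim, n_heads, rng, dtype=dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)
        self.fc1 = Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(gelu(self.fc1(self.norm2(x))))
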