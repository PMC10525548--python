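"""Neural-network layers built on the :mod:`medcap._tensor` engine.

Dense, layer normalisation, embeddings, multi-head attention and a small
3x3 'same' convolution with average pooling — the building blocks of the
caption transcoder and of the ``tiny_cnn`` backbone.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = [
    "Module",
    "Dense",
    "LayerNorm",
    "Embedding",
    "MultiHeadAttention",
    "Conv2d",
    "avg_pool2",
]


class Module:
    """Base class: tracks parameters (and submodules) by name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.b = Tensor(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    """Layer normalisation over the last axis with learnable scale/shift."""

    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = Tensor(rng.normal(0.0, 0.02, size=(n, dim)))

    def __call__(self, indices) -> Tensor:
        return self.table.embedding(indices)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``n_heads`` parallel heads.

    Accepts inputs of shape (..., L, embed_dim); an optional additive mask
    broadcastable to (..., heads, L_q, L_k) implements causal masking.
    """

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.wq = Dense(embed_dim, embed_dim, rng)
        self.wk = Dense(embed_dim, embed_dim, rng)
        self.wv = Dense(embed_dim, embed_dim, rng)
        self.wo = Dense(embed_dim, embed_dim, rng)

    def _split(self, x: Tensor) -> Tensor:
        *batch, L, d = x.shape
        x = x.reshape(*batch, L, self.n_heads, self.head_dim)
        axes = tuple(range(len(batch))) + (len(batch) + 1, len(batch), len(batch) + 2)
        return x.transpose(axes)  # (..., heads, L, head_dim)

    def _merge(self, x: Tensor) -> Tensor:
        *batch, h, L, hd = x.shape
        axes = tuple(range(len(batch))) + (len(batch) + 1, len(batch), len(batch) + 2)
        return x.transpose(axes).reshape(*batch, L, h * hd)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor, mask=None) -> Tensor:
        q = self._split(self.wq(query))
        k = self._split(self.wk(key))
        v = self._split(self.wv(value))
        scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) / np.sqrt(
            self.head_dim
        )
        if mask is not None:
            scores = scores + np.asarray(mask)
        attn = scores.softmax()
        return self.wo(self._merge(attn @ v))


class Conv2d(Module):
    """3x3 'same' convolution over (B, H, W, C) maps via patch extraction."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, ksize: int = 3):
        super().__init__()
        self.ksize = ksize
        self.in_ch = in_ch
        fan = ksize * ksize * in_ch
        self.w = Tensor(_glorot(rng, fan, out_ch, (fan, out_ch)))
        self.b = Tensor(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        k = self.ksize
        pad = k // 2
        Hp, Wp = H + 2 * pad, W + 2 * pad

        padded = np.zeros((B, Hp, Wp, C))
        padded[:, pad : pad + H, pad : pad + W, :] = x.data
        src = x  # closure reference for backward

        # gather indices into the flattened (Hp*Wp) plane
        rows = np.arange(H)[:, None, None, None] + np.arange(k)[None, None, :, None]
        cols = np.arange(W)[None, :, None, None] + np.arange(k)[None, None, None, :]
        flat = (rows * Wp + cols).reshape(H, W, k * k)

        patches_data = padded.reshape(B, Hp * Wp, C)[:, flat, :].reshape(B, H, W, k * k * C)
        patches = Tensor(patches_data, (src,))

        def bwd(g):
            gpad = np.zeros((B, Hp * Wp, C))
            np.add.at(gpad, (slice(None), flat), g.reshape(B, H, W, k * k, C))
            gpad = gpad.reshape(B, Hp, Wp, C)
            src._accumulate(gpad[:, pad : pad + H, pad : pad + W, :])

        patches._backward = bwd
        return patches @ self.w + self.b


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling of a (B, H, W, C) map; H and W must be even."""
    B, H, W, C = x.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    x = x.reshape(B, H // 2, 2, W // 2, 2, C)
    return x.mean(axis=2).mean(axis=3)
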