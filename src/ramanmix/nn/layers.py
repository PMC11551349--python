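"""Neural-network layers on top of the autograd core.

Initialization is Glorot-uniform from a layer-local ``numpy`` Generator so
that a model built from a fixed seed is bit-reproducible.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .autograd import Tensor, concat, conv1d

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
]


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        super().__init__()
        self.W = self.register(
            "W", _glorot(rng, in_features, out_features, (in_features, out_features))
        )
        self.b = self.register("b", np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out if self.b is None else out + self.b


class Conv1d(Module):
    """Same-padded 1-D convolution layer, (B, C_in, L) -> (B, C_out, L)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.W = self.register(
            "W", _glorot(rng, fan_in, fan_out, (out_channels, in_channels, kernel_size))
        )
        self.b = self.register("b", np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(dim))
        self.beta = self.register("beta", np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2.0).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout with a module-local seeded mask stream."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Self-attention with ``n_heads`` heads of dimension ``head_dim``.

    Input/output shape (B, T, embed_dim); queries, keys and values are
    linear projections to n_heads * head_dim, and the concatenated head
    outputs are projected back to embed_dim.
    """

    def __init__(
        self, embed_dim: int, n_heads: int, head_dim: int, rng: np.random.Generator
    ):
        super().__init__()
        inner = n_heads * head_dim
        self.n_heads = n_heads
        self.head_dim = head_dim
        self.q_proj = Linear(embed_dim, inner, rng)
        self.k_proj = Linear(embed_dim, inner, rng)
        self.v_proj = Linear(embed_dim, inner, rng)
        self.out_proj = Linear(inner, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h, d = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B, T, h*d) -> (B, h, T, d)
            return t.reshape(B, T, h, d).swapaxes(1, 2)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))  # (B, h, T, T)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, h, T, d)
        merged = out.swapaxes(1, 2).reshape(B, T, h * d)
        return self.out_proj(merged)
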