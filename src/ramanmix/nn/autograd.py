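"""Minimal reverse-mode automatic differentiation over numpy arrays.

A ``Tensor`` wraps an ndarray and records the operation that produced it;
``Tensor.backward()`` walks the tape in reverse topological order and
accumulates gradients into every tensor with ``requires_grad=True``.  The
op set is exactly what the unmixing autoencoders need: broadcast
arithmetic, (batched) matmul, reductions, the nonlinearities, softmax,
a clipped arccos for the spectral-angle loss, 1-D convolution, and the
shape plumbing (reshape / transpose / concatenate / slicing).

Gradients follow numpy broadcasting semantics: contributions along
broadcast axes are summed back to the parent's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # Sum leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(
            data,
            requires_grad=req,
            _parents=tuple(parents) if req else (),
            _backward=backward if req else None,
        )

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * Tensor._wrap(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._wrap(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        return self**0.5

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.02) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self) -> "Tensor":
        """log(1 + e^x), computed stably; gradient is the sigmoid."""
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    def acos_clipped(self, eps: float = 1e-7) -> "Tensor":
        """arccos with the argument clipped to [-1+eps, 1-eps].

        Keeps the gradient ``-1/sqrt(1-u^2)`` finite at the boundaries; the
        gradient is zero where the input was clipped (flat region of clip).
        """
        clipped = np.clip(self.data, -1.0 + eps, 1.0 - eps)
        inside = np.abs(self.data) < 1.0 - eps
        out_data = np.arccos(clipped)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.where(inside, -g / np.sqrt(1.0 - clipped**2), 0.0))

        return Tensor._make(out_data, (self,), backward)

    # -- shape plumbing ----------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        axes = axes or None
        out_data = self.data.transpose(axes) if axes else self.data.T
        inv = np.argsort(axes) if axes else None

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv) if inv is not None else g.T)

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tensors, backward)


def conv1d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """Same-padded 1-D convolution (cross-correlation).

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, K) with odd K;
    ``bias``: (C_out,).  Output: (B, C_out, L).
    """
    B, C_in, L = x.shape
    C_out, C_in_w, K = weight.shape
    if C_in_w != C_in:
        raise ValueError(f"channel mismatch: input {C_in}, weight {C_in_w}")
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel size")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # windows: (B, C_in, L, K)
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    out_data = np.einsum("bclk,ock->bol", windows, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("bclk,bol->ock", windows, g, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (pad, pad)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=2)
            # full correlation with the flipped kernel
            w_flip = weight.data[:, :, ::-1]
            gx = np.einsum("bolk,ock->bcl", gwin, w_flip, optimize=True)
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)
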