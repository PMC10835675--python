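"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides exactly the tensor operations the depth model needs:
dense matmul (with broadcast batch dimensions), embedding lookup, layer
normalization, masked softmax attention, GELU/ReLU, dropout and a handful
of shape ops. Gradients are accumulated through a dynamically built tape,
micrograd-style, but on ndarrays with float32 storage so that training a
small transformer stays fast on a single CPU core.

Only what the model uses is implemented; this is not a general framework.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "reshape",
    "transpose",
    "concat",
    "take_index",
    "relu",
    "gelu",
    "embedding",
    "layer_norm",
    "masked_softmax",
    "dropout",
    "masked_mean_pool",
    "ssum",
    "mse",
    "AdamW",
    "clip_grad_norm",
]

_F32 = np.float32


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = True,
    ) -> None:
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=_F32)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seeding with ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=_F32), requires_grad=False)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=_F32), requires_grad=True)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return Tensor(out_data, (a, b), backward, _needs_grad(a, b))


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g: np.ndarray) -> None:
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(-g, b.shape))

    return Tensor(out_data, (a, b), backward, _needs_grad(a, b))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, (a, b), backward, _needs_grad(a, b))


def scale(a: Tensor, s: float) -> Tensor:
    out_data = a.data * _F32(s)

    def backward(g: np.ndarray) -> None:
        _accumulate(a, g * _F32(s))

    return Tensor(out_data, (a,), backward, a.requires_grad)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            _accumulate(a, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            _accumulate(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return Tensor(out_data, (a, b), backward, _needs_grad(a, b))


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g: np.ndarray) -> None:
        _accumulate(a, g.reshape(a.shape))

    return Tensor(out_data, (a,), backward, a.requires_grad)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g: np.ndarray) -> None:
        _accumulate(a, g.transpose(inv))

    return Tensor(out_data, (a,), backward, a.requires_grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return Tensor(out_data, tuple(tensors), backward, _needs_grad(*tensors))


def take_index(a: Tensor, index: int, axis: int = 1) -> Tensor:
    """Select one slice along ``axis`` (used for first-token pooling)."""
    out_data = np.take(a.data, index, axis=axis)

    def backward(g: np.ndarray) -> None:
        buf = np.zeros_like(a.data)
        idx = [slice(None)] * a.data.ndim
        idx[axis] = index
        buf[tuple(idx)] = g
        _accumulate(a, buf)

    return Tensor(out_data, (a,), backward, a.requires_grad)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def backward(g: np.ndarray) -> None:
        _accumulate(a, g * (a.data > 0))

    return Tensor(out_data, (a,), backward, a.requires_grad)


_GELU_C = _F32(np.sqrt(2.0 / np.pi))
_GELU_A = _F32(0.044715)


def gelu(a: Tensor) -> Tensor:
    """GELU via the standard tanh approximation (BERT convention)."""
    x = a.data
    u = _GELU_C * (x + _GELU_A * x * x * x)
    t = np.tanh(u)
    out_data = _F32(0.5) * x * (_F32(1.0) + t)

    def backward(g: np.ndarray) -> None:
        du = _GELU_C * (_F32(1.0) + _F32(3.0) * _GELU_A * x * x)
        d = _F32(0.5) * (_F32(1.0) + t) + _F32(0.5) * x * (_F32(1.0) - t * t) * du
        _accumulate(a, g * d)

    return Tensor(out_data, (a,), backward, a.requires_grad)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]``; backward scatter-adds into the table."""
    out_data = table.data[ids]

    def backward(g: np.ndarray) -> None:
        buf = np.zeros_like(table.data)
        np.add.at(buf, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        _accumulate(table, buf)

    return Tensor(out_data, (table,), backward, table.requires_grad)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out_data = gamma.data * xhat + beta.data

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            _accumulate(gamma, _unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            _accumulate(beta, _unbroadcast(g, beta.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            dx = (
                dxhat
                - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
            ) * inv_std
            _accumulate(x, dx.astype(_F32, copy=False))

    return Tensor(out_data.astype(_F32, copy=False), (x, gamma, beta), backward,
                  _needs_grad(x, gamma, beta))


def masked_softmax(scores: Tensor, key_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis with invalid keys excluded.

    ``scores`` has shape (B, H, Tq, Tk); ``key_mask`` is boolean (B, Tk),
    True where the key position is a real token.
    """
    m = key_mask[:, None, None, :]
    s = np.where(m, scores.data, _F32(-1e9))
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    p = (e / e.sum(axis=-1, keepdims=True)).astype(_F32)

    def backward(g: np.ndarray) -> None:
        ds = p * (g - (g * p).sum(axis=-1, keepdims=True))
        _accumulate(scores, ds.astype(_F32, copy=False))

    return Tensor(p, (scores,), backward, scores.requires_grad)


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    keep = (rng.random(x.shape, dtype=_F32) >= p).astype(_F32) / _F32(1.0 - p)
    out_data = x.data * keep

    def backward(g: np.ndarray) -> None:
        _accumulate(x, g * keep)

    return Tensor(out_data, (x,), backward, x.requires_grad)


def masked_mean_pool(x: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over valid positions; ``x`` is (B, T, D), ``mask`` boolean (B, T)."""
    w = mask.astype(_F32)
    counts = w.sum(axis=1, keepdims=True)  # (B, 1)
    out_data = (x.data * w[:, :, None]).sum(axis=1) / counts

    def backward(g: np.ndarray) -> None:
        _accumulate(x, (g[:, None, :] * w[:, :, None] / counts[:, :, None]).astype(_F32))

    return Tensor(out_data.astype(_F32), (x,), backward, x.requires_grad)


def ssum(a: Tensor) -> Tensor:
    out_data = np.asarray(a.data.sum(), dtype=_F32)

    def backward(g: np.ndarray) -> None:
        _accumulate(a, np.broadcast_to(g, a.shape).astype(_F32))

    return Tensor(out_data, (a,), backward, a.requires_grad)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error between predictions and a constant target vector."""
    if pred.data.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {target.shape}")
    n = pred.data.shape[0]
    if n == 0:
        raise ValueError("empty input")
    diff = pred.data - target
    out_data = np.asarray((diff * diff).mean(), dtype=_F32)

    def backward(g: np.ndarray) -> None:
        _accumulate(pred, (g * 2.0 * diff / n).astype(_F32))

    return Tensor(out_data, (pred,), backward, pred.requires_grad)


class AdamW:
    """AdamW with decoupled weight decay and bias correction."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = (p.data - self.lr * update).astype(_F32)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    grads = [p.grad for p in params if p.grad is not None]
    if not grads:
        return 0.0
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm > 0:
        factor = _F32(max_norm / (total + 1e-12))
        for g in grads:
            g *= factor
    return total
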