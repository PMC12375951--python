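"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small transformer encoder trained with RMSprop:
broadcasting arithmetic, (batched) matmul, softmax, layer norm, embedding
lookup, dropout, and a piecewise "wiggle" output transform.  Gradients are
accumulated lazily (no dense zero-fill pass) by topological-order
backpropagation; correctness is checked against central finite differences
in the test suite.  ``no_grad()`` disables graph construction for
evaluation-mode forward passes.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (evaluation-mode forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def accum(self, g: np.ndarray):
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, release: bool = True):
        """Backpropagate to all reachable parameters.

        ``release`` breaks the closure reference cycles afterwards so graph
        activations are freed immediately instead of waiting for the cyclic
        garbage collector (they can be gigabytes).
        """
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward()
        if release:
            for t in order:
                t._parents = ()
                t._backward = None


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out = Tensor(data, requires_grad=True)
        out._parents = tuple(parents)
        out._backward = backward
        return out
    return Tensor(data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward():
        if a.requires_grad:
            a.accum(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b.accum(_unbroadcast(out.grad, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward():
        if a.requires_grad:
            a.accum(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b.accum(_unbroadcast(out.grad * a.data, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward():
        if a.requires_grad:
            a.accum(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b.accum(_unbroadcast(-out.grad, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward():
        if a.requires_grad:
            a.accum(_unbroadcast(out.grad @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b.accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ out.grad, b.shape))

    out = _make(out_data, (a, b), backward)
    return out


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)

    def backward():
        if a.requires_grad:
            a.accum(np.transpose(out.grad, inv))

    out = _make(np.transpose(a.data, axes), (a,), backward)
    return out


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def backward():
        if a.requires_grad:
            a.accum(out.grad.reshape(a.shape))

    out = _make(np.ascontiguousarray(a.data).reshape(shape), (a,), backward)
    return out


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward():
        if a.requires_grad:
            a.accum(out.grad * out_data)

    out = _make(out_data, (a,), backward)
    return out


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward():
        if a.requires_grad:
            a.accum(out.grad / a.data)

    out = _make(np.log(a.data), (a,), backward)
    return out


def relu(a) -> Tensor:
    a = _as_tensor(a)
    keep = a.data > 0

    def backward():
        if a.requires_grad:
            a.accum(out.grad * keep)

    out = _make(a.data * keep, (a,), backward)
    return out


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes through only inside the interval."""
    a = _as_tensor(a)
    inside = (a.data > lo) & (a.data < hi)

    def backward():
        if a.requires_grad:
            a.accum(out.grad * inside)

    out = _make(np.clip(a.data, lo, hi), (a,), backward)
    return out


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted, out=shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward():
        if a.requires_grad:
            g = out.grad
            a.accum(out_data * (g - (g * out_data).sum(axis=axis, keepdims=True)))

    out = _make(out_data, (a,), backward)
    return out


def layer_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x, gain, bias = _as_tensor(x), _as_tensor(gain), _as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward():
        g = out.grad
        if gain.requires_grad:
            gain.accum(_unbroadcast(g * xhat, gain.shape))
        if bias.requires_grad:
            bias.accum(_unbroadcast(g, bias.shape))
        if x.requires_grad:
            dxhat = g * gain.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x.accum(inv * (dxhat - m1 - xhat * m2))

    out = _make(xhat * gain.data + bias.data, (x, gain, bias), backward)
    return out


def embedding(table, idx: np.ndarray) -> Tensor:
    """Row lookup ``table[idx]``; gradients scatter-add back into the table."""
    table = _as_tensor(table)
    idx = np.asarray(idx)

    def backward():
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, idx, out.grad)
            table.accum(g)

    out = _make(table.data[idx], (table,), backward)
    return out


def take_rows(a, idx: np.ndarray) -> Tensor:
    """``a[idx]`` along axis 0 (used to fan one parent out to many PCPs)."""
    return embedding(a, idx)


def dropout(a, p: float, rng: np.random.Generator) -> Tensor:
    a = _as_tensor(a)
    if p <= 0:
        return a
    keep = (rng.random(a.shape, dtype=np.float32) >= p) / np.float32(1.0 - p)

    def backward():
        if a.requires_grad:
            a.accum(out.grad * keep)

    out = _make(a.data * keep, (a,), backward)
    return out


def sum_all(a) -> Tensor:
    a = _as_tensor(a)

    def backward():
        if a.requires_grad:
            a.accum(np.broadcast_to(out.grad, a.shape))

    out = _make(a.data.sum(), (a,), backward)
    return out


def exp_wiggle_op(a, beta: float) -> Tensor:
    """Piecewise output transform: exp(beta (x-1)) below 1, x**beta above.

    Continuous and strictly increasing with value 1 at x = 1; growth above 1
    is sub-linear so selection factors stay in a reasonable range.
    """
    a = _as_tensor(a)
    x = a.data
    lower = x < 1.0
    xc = np.maximum(x, 1.0)
    out_data = np.where(lower, np.exp(beta * (x - 1.0)), np.power(xc, beta))

    def backward():
        if a.requires_grad:
            deriv = np.where(lower, beta * out_data, beta * np.power(xc, beta - 1.0))
            a.accum(out.grad * deriv)

    out = _make(out_data.astype(x.dtype, copy=False), (a,), backward)
    return out


class RMSprop:
    """RMSprop with running squared-gradient average and global-norm clipping."""

    def __init__(self, params, lr: float = 1e-3, alpha: float = 0.99,
                 eps: float = 1e-8, clip_norm: float = 1.0):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.clip_norm = clip_norm
        self.sq = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        live = [(p, sq) for p, sq in zip(self.params, self.sq) if p.grad is not None]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum())
                                for p, _ in live))
            scale = 1.0 if total <= self.clip_norm else self.clip_norm / (total + 1e-12)
        else:
            scale = 1.0
        for p, sq in live:
            g = p.grad.astype(np.float64) * scale
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data = (p.data - self.lr * g / (np.sqrt(sq) + self.eps)).astype(
                p.data.dtype, copy=False
            )


def grad_check(f, params: list[Tensor], eps: float = 1e-5) -> float:
    """Max relative error between backprop and central finite differences."""
    loss = f()
    for p in params:
        p.zero_grad()
    loss.backward()
    worst = 0.0
    for p in params:
        flat = p.data.reshape(-1)
        gflat = (p.grad if p.grad is not None else np.zeros_like(p.data)).reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(f().data)
            flat[i] = orig - eps
            lo = float(f().data)
            flat[i] = orig
            fd = (hi - lo) / (2 * eps)
            denom = max(abs(fd), abs(gflat[i]), 1e-8)
            worst = max(worst, abs(fd - gflat[i]) / denom)
    return worst
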