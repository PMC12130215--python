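"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the population decoder needs: affine maps,
GeLU, layer normalisation, masked softmax attention, dropout (as multiplication
by a precomputed mask), masked max-pooling and a fused softmax cross-entropy.
Differentiable inputs are :class:`Tensor`; constants are plain ndarrays.

Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Tensor:
    """A node in the computation graph: a float64 array plus backward closure."""

    __slots__ = ("value", "grad", "_parents", "_bwd")

    def __init__(self, value, parents=(), bwd=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bwd = bwd

    @property
    def shape(self):
        return self.value.shape


def _acc(t: Tensor, g: np.ndarray) -> None:
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value + b.value, (a, b))

    def bwd(g):
        _acc(a, _unbroadcast(g, a.value.shape))
        _acc(b, _unbroadcast(g, b.value.shape))

    out._bwd = bwd
    return out


def add_const(a: Tensor, c) -> Tensor:
    out = Tensor(a.value + c, (a,))
    out._bwd = lambda g: _acc(a, _unbroadcast(g, a.value.shape))
    return out


def mul_const(a: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=np.float64)
    out = Tensor(a.value * c, (a,))
    out._bwd = lambda g: _acc(a, _unbroadcast(g * c, a.value.shape))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value @ b.value, (a, b))

    def bwd(g):
        ga = g @ np.swapaxes(b.value, -1, -2)
        gb = np.swapaxes(a.value, -1, -2) @ g
        if ga.ndim > a.value.ndim:
            ga = ga.sum(axis=tuple(range(ga.ndim - a.value.ndim)))
        if gb.ndim > b.value.ndim:
            gb = gb.sum(axis=tuple(range(gb.ndim - b.value.ndim)))
        _acc(a, ga)
        _acc(b, gb)

    out._bwd = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add(matmul(x, w), b)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    v = x.value
    cdf = 0.5 * (1.0 + erf(v / _SQRT2))
    out = Tensor(v * cdf, (x,))

    def bwd(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * v * v)
        _acc(x, g * (cdf + v * pdf))

    out._bwd = bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    v = x.value
    mu = v.mean(axis=-1, keepdims=True)
    var = v.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (v - mu) * inv
    out = Tensor(gamma.value * xhat + beta.value, (x, gamma, beta))

    def bwd(g):
        d = v.shape[-1]
        dxhat = g * gamma.value
        gx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        _acc(x, gx)
        _acc(gamma, _unbroadcast(g * xhat, gamma.value.shape))
        _acc(beta, _unbroadcast(g, beta.value.shape))

    out._bwd = bwd
    return out


def softmax_last(x: Tensor) -> Tensor:
    v = x.value
    m = np.max(v, axis=-1, keepdims=True)
    # fully-masked rows (all -inf) would yield NaN; guard with finite max
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(v - m)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, (x,))

    def bwd(g):
        _acc(x, s * (g - (g * s).sum(axis=-1, keepdims=True)))

    out._bwd = bwd
    return out


def max_last_axis2(x: Tensor) -> Tensor:
    """Max over axis -2 (the token axis of a (..., N, D) tensor).

    Gradient flows to the first argmax along that axis.
    """
    v = x.value
    idx = np.argmax(v, axis=-2)
    out_val = np.max(v, axis=-2)
    out = Tensor(out_val, (x,))

    def bwd(g):
        gx = np.zeros_like(v)
        np.put_along_axis(gx, idx[..., None, :], g[..., None, :], axis=-2)
        _acc(x, gx)

    out._bwd = bwd
    return out


def reshape(x: Tensor, shape) -> Tensor:
    out = Tensor(x.value.reshape(shape), (x,))
    out._bwd = lambda g: _acc(x, g.reshape(x.value.shape))
    return out


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    out = Tensor(x.value.transpose(axes), (x,))
    out._bwd = lambda g: _acc(x, g.transpose(inv))
    return out


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy, in nats. ``labels`` is an int array (B,)."""
    v = logits.value
    m = v.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(v - m).sum(axis=-1, keepdims=True))
    logp = v - lse
    n = v.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = Tensor(loss, (logits,))

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        _acc(logits, g * p / n)

    out._bwd = bwd
    return out


def backward(loss: Tensor) -> None:
    """Accumulate gradients of ``loss`` into every reachable Tensor's ``.grad``."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    for t in topo:
        t.grad = None
    loss.grad = np.ones_like(loss.value)
    for t in reversed(topo):
        if t._bwd is not None and t.grad is not None:
            t._bwd(t.grad)
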