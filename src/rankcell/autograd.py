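"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the transformer encoder needs: broadcasted
arithmetic, batched matmul, reshape/transpose, embedding lookup, softmax,
layer normalization, SiLU/GELU-free activations, dropout, reductions and a
fused softmax cross-entropy. Gradients are accumulated in float32.

A module-level ``no_grad()`` context disables graph construction so that
inference runs at plain-numpy speed.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_borrowed = False

    # -- graph bookkeeping ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # copy-on-write: a first contribution is adopted without copying (it
        # may alias another node's grad); only a second contribution forces a
        # fresh array, so shared arrays are never mutated in place
        if self.grad is None:
            self.grad = g if g.dtype == np.float32 else g.astype(np.float32)
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # free graph references as we go
            node._backward = None
            node._parents = ()

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Iterable[Tensor]) -> Tensor:
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data + b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.data.shape))
        out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data * b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.data.shape))
        out._backward = _bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(a.data @ b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                ga = out.grad @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ out.grad
                b._accum(_unbroadcast(gb, b.data.shape))
        out._backward = _bw
    return out


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    out = _make(a.data.reshape(shape), (a,))
    if out.requires_grad:
        def _bw():
            a._accum(out.grad.reshape(a.data.shape))
        out._backward = _bw
    return out


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    out = _make(np.transpose(a.data, axes), (a,))
    if out.requires_grad:
        inv = np.argsort(axes)
        def _bw():
            a._accum(np.transpose(out.grad, inv))
        out._backward = _bw
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = _make(table.data[ids], (table,))
    if out.requires_grad:
        def _bw():
            g = np.zeros_like(table.data)
            np.add.at(g, ids.reshape(-1), out.grad.reshape(-1, table.data.shape[-1]))
            table._accum(g)
        out._backward = _bw
    return out


def silu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    sig = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(a.data * sig, (a,))
    if out.requires_grad:
        def _bw():
            a._accum(out.grad * (sig * (1.0 + a.data * (1.0 - sig))))
        out._backward = _bw
    return out


def softmax(a: Tensor) -> Tensor:
    """Softmax over the last axis."""
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = _make(s, (a,))
    if out.requires_grad:
        def _bw():
            g = out.grad
            dot = (g * s).sum(axis=-1, keepdims=True)
            a._accum(s * (g - dot))
        out._backward = _bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if x.requires_grad:
                n = x.data.shape[-1]
                gx = g * gamma.data
                dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                            - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
                x._accum(dx)
                del n
        out._backward = _bw
    return out


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    a = _as_tensor(a)
    if rate <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    out = _make(a.data * mask, (a,))
    if out.requires_grad:
        def _bw():
            a._accum(out.grad * mask)
        out._backward = _bw
    return out


def mean_all(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = _make(np.asarray(a.data.mean()), (a,))
    if out.requires_grad:
        def _bw():
            a._accum(np.full_like(a.data, out.grad / a.data.size))
        out._backward = _bw
    return out


def take_rows(a: Tensor, idx0: np.ndarray, idx1: np.ndarray) -> Tensor:
    """Gather ``a[idx0, idx1, :]`` from a 3-D tensor."""
    out = _make(a.data[idx0, idx1], (a,))
    if out.requires_grad:
        def _bw():
            g = np.zeros_like(a.data)
            np.add.at(g, (idx0, idx1), out.grad)
            a._accum(g)
        out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of ``logits`` (N, V) against integer ``targets``."""
    logits = _as_tensor(logits)
    targets = np.asarray(targets)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    loss = float((lse - z[np.arange(n), targets]).mean())
    out = _make(np.asarray(loss, dtype=np.float32), (logits,))
    if out.requires_grad:
        def _bw():
            p = np.exp(z - lse[:, None])
            p[np.arange(n), targets] -= 1.0
            logits._accum((out.grad * p / n).astype(np.float32))
        out._backward = _bw
    return out


class AdamW:
    """Decoupled weight-decay Adam on a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-3):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m, v = self._m[k], self._v[k]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * (p.grad * p.grad)
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                upd += self.weight_decay * p.data
            p.data -= np.float32(lr) * upd

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def numerical_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                       eps: float = 1e-3) -> np.ndarray:
    """Central finite differences; test helper for gradient checks."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x.astype(np.float32))
        x[i] = orig - eps
        fm = f(x.astype(np.float32))
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
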