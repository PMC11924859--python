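"""Minimal reverse-mode automatic differentiation over numpy arrays.

Backs the character-level table language model (:mod:`rte.table_lm`) and the
recurrent line classifier (:mod:`rte.page_detect`).  Only the operations those
models need are implemented: broadcast-aware add/mul, (batched) matmul,
pointwise nonlinearities, softmax, layer normalization, embedding lookup,
shape ops, and the two loss heads.  float32 throughout; gradients accumulate
into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "seeded_rng"]


def seeded_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) % (2**31))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._bw = bw if self.requires_grad else None

    # -- graph machinery ---------------------------------------------------
    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            out = Tensor(self.data + other, parents=(self,))
            out._bw = lambda g: self._accum(_unbroadcast(g, self.data.shape))
            return out
        a, b = self, other
        out = Tensor(a.data + b.data, parents=(a, b))

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        out._bw = bw
        return out

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            out = Tensor(self.data * other, parents=(self,))
            out._bw = lambda g: self._accum(_unbroadcast(g * other, self.data.shape))
            return out
        a, b = self, other
        out = Tensor(a.data * b.data, parents=(a, b))

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        out._bw = bw
        return out

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-other if isinstance(other, Tensor) else -other)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))

        out._bw = bw
        return out

    __matmul__ = matmul

    # -- nonlinearities ------------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._bw = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._bw = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation (standard GPT practice)
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        y = 0.5 * x * (1.0 + t)
        out = Tensor(y, parents=(self,))

        def bw(g):
            dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x**2)
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        out._bw = bw
        return out

    def softmax(self) -> "Tensor":
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, parents=(self,))

        def bw(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            self._accum(y * (g - dot))

        out._bw = bw
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._bw = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        out._bw = lambda g: self._accum(g.transpose(*inv))
        return out

    def narrow(self, axis: int, start: int, size: int) -> "Tensor":
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + size)
        idx = tuple(idx)
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._bw = bw
        return out


# ---------------------------------------------------------------------------
# composite / fused operations
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(offset, offset + s)
            if t.requires_grad:
                t._accum(g[tuple(idx)])
            offset += s

    out._bw = bw
    return out


def layernorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    n = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx_hat = g * gamma.data
            term = gx_hat - gx_hat.mean(axis=-1, keepdims=True)
            term -= xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            x._accum(term * inv)

    out._bw = bw
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(weight.data[ids], parents=(weight,))

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.data.shape[-1]))
        weight._accum(full)

    out._bw = bw
    return out


def take_positions(x: Tensor, positions: np.ndarray) -> Tensor:
    """out[b] = x[b, positions[b], :] — per-sequence final-position gather."""
    pos = np.asarray(positions, dtype=np.int64)
    batch = np.arange(x.data.shape[0])
    out = Tensor(x.data[batch, pos], parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[batch, pos] = g
        x._accum(full)

    out._bw = bw
    return out


def add_mask(x: Tensor, mask: np.ndarray) -> Tensor:
    """Add a constant additive mask (e.g. the causal -inf triangle)."""
    out = Tensor(x.data + mask, parents=(x,))
    out._bw = lambda g: x._accum(g)
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean next-token cross entropy.  logits (N, V); targets (N,) int ids."""
    targets = np.asarray(targets, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    n = targets.shape[0]
    loss = -logp[np.arange(n), targets].mean()
    out = Tensor(loss, parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), targets] -= 1.0
        logits._accum(g * p / n)

    out._bw = bw
    return out


def bce_logits(logits: Tensor, labels: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean class-weighted binary cross entropy on raw logits (any shape)."""
    y = np.asarray(labels, dtype=np.float32).reshape(logits.data.shape)
    z = logits.data
    p = 1.0 / (1.0 + np.exp(-z))
    eps = 1e-12
    w = np.where(y > 0.5, np.float32(pos_weight), np.float32(1.0))
    loss = -(w * (y * np.log(p + eps) + (1.0 - y) * np.log(1.0 - p + eps))).mean()
    out = Tensor(loss, parents=(logits,))
    n = y.size

    def bw(g):
        logits._accum(g * w * (p - y) / n)

    out._bw = bw
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Standard Adam (bias-corrected first/second moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
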