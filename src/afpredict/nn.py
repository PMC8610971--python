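"""Minimal reverse-mode automatic differentiation and neural-network building blocks.

The AF-score networks in :mod:`afpredict.models` are small 1-D convolutional /
recurrent architectures trained on desk-scale synthetic cohorts, so a compact
numpy engine is sufficient: tensors carry a ``data`` array and, when gradients
are enabled, a closure that propagates the upstream gradient to their parents.
Convolution and batch normalisation are implemented as fused primitives with
hand-derived backward passes (verified against finite differences in the test
suite); everything else is composed from elementwise primitives.

Only what the models need is implemented: broadcasting elementwise arithmetic,
matmul, 1-D same-padding convolution, batch norm, LSTM cells built from
primitives, max pooling, reductions, and a numerically stable binary
cross-entropy on logits.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(DTYPE)
    return a


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
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
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

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    parents = [p for p in parents if isinstance(p, Tensor)]
    track = _grad_enabled and any(p.requires_grad or p._parents for p in parents)
    if not track:
        return Tensor(data)
    return Tensor(data, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# elementwise / structural primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bwd(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    return _make(out_data, (a, b), bwd)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        a.accumulate(g * mask)

    return _make(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

    def bwd(g):
        a.accumulate(g * s * (1.0 - s))

    return _make(s, (a,), bwd)


def tanh(a) -> Tensor:
    a = _wrap(a)
    t = np.tanh(a.data)

    def bwd(g):
        a.accumulate(g * (1.0 - t * t))

    return _make(t, (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        a.accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), bwd)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = a.data.transpose(axes)

    def bwd(g):
        a.accumulate(g.transpose(inv))

    return _make(out_data, (a,), bwd)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, np.integer, slice)) for i in items)


def getitem(a, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]
    basic = _is_basic_index(idx)  # basic indices never alias: plain add is safe

    def bwd(g):
        full = np.zeros_like(a.data)
        if basic:
            full[idx] += g
        else:
            np.add.at(full, idx, g)
        a.accumulate(full)

    return _make(out_data, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.accumulate(g[tuple(sl)])

    return _make(out_data, tensors, bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            t.accumulate(p.reshape(t.data.shape))

    return _make(out_data, tensors, bwd)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        a.accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), bwd)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reduce_max(a, axis: int) -> Tensor:
    a = _wrap(a)
    arg = a.data.argmax(axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(arg, axis),
                                  axis=axis).squeeze(axis)

    def bwd(g):
        # gradient flows to the (first) argmax position only
        full = np.zeros_like(a.data)
        np.put_along_axis(full, np.expand_dims(arg, axis),
                          np.expand_dims(g, axis), axis=axis)
        a.accumulate(full)

    return _make(out_data, (a,), bwd)


# ---------------------------------------------------------------------------
# fused primitives
# ---------------------------------------------------------------------------

def conv1d(x, w, b, padding: str = "same") -> Tensor:
    """1-D convolution (cross-correlation) along the last axis.

    x: (N, C, L); w: (F, C, K); b: (F,). Stride 1, 'same' zero padding.
    """
    x, w, b = _wrap(x), _wrap(w), _wrap(b)
    N, C, L = x.data.shape
    F, C2, K = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    pl = (K - 1) // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    # conv as K shifted batched matmuls: much cheaper than im2col for small K
    wt = w.data.transpose(2, 1, 0)                       # (K, C, F)
    acc = np.zeros((N, L, F), dtype=x.data.dtype)
    for k in range(K):
        acc += xp[:, :, k:k + L].transpose(0, 2, 1) @ wt[k]
    y = acc.transpose(0, 2, 1) + b.data[None, :, None]

    def bwd(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, L, F)
        g2 = gl.reshape(N * L, F)
        dw = np.empty_like(w.data)
        dxp = np.zeros_like(xp)
        for k in range(K):
            xs = xp[:, :, k:k + L].transpose(0, 2, 1).reshape(N * L, C)
            dw[:, :, k] = (xs.T @ g2).T                  # (F, C)
            dxp[:, :, k:k + L] += (gl @ wt[k].T).transpose(0, 2, 1)
        w.accumulate(dw)
        b.accumulate(g.sum(axis=(0, 2)))
        x.accumulate(dxp[:, :, pl:pl + L])

    return _make(y, (x, w, b), bwd)


def batch_norm(x, gamma, beta, eps: float = 1e-5):
    """Training-mode batch normalisation over all axes except channel axis 1.

    Returns ``(y, batch_mean, batch_var)``; the statistics are plain arrays for
    the caller to fold into running estimates.
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = tuple(i for i in range(x.data.ndim) if i != 1)
    m = x.data.mean(axis=axes, keepdims=True)
    v = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m) * inv
    shape = [1] * x.data.ndim
    shape[1] = -1
    gam = gamma.data.reshape(shape)
    y = gam * xhat + beta.data.reshape(shape)
    n = x.data.size / x.data.shape[1]

    def bwd(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        dxhat = g * gam
        t1 = dxhat.sum(axis=axes, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        x.accumulate(inv / n * (n * dxhat - t1 - xhat * t2))

    out = _make(y, (x, gamma, beta), bwd)
    return out, m.reshape(-1), v.reshape(-1)


def bce_with_logits(logits, targets) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    logits = _wrap(logits)
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out_data = loss.mean()
    s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def bwd(g):
        logits.accumulate(g * (s - t) / z.size)

    return _make(out_data, (logits,), bwd)


def dropout(x, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0:
        return _wrap(x)
    x = _wrap(x)
    mask = ((rng.random(x.data.shape, dtype=np.float32) >= rate)
            .astype(x.data.dtype) / (1.0 - rate))

    def bwd(g):
        x.accumulate(g * mask)

    return _make(x.data * mask, (x,), bwd)


def gaussian_noise(x, sigma: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Additive Gaussian noise regulariser (identity at inference)."""
    if not train or sigma <= 0:
        return _wrap(x)
    x = _wrap(x)
    noise = sigma * rng.standard_normal(x.data.shape, dtype=np.float32)

    def bwd(g):
        x.accumulate(g)

    return _make(x.data + noise, (x,), bwd)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


def _param(shape, rng: np.random.Generator, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, shape).astype(DTYPE), requires_grad=True)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = _param((out_ch, in_ch, kernel), rng, scale)
        self.b = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)

    def __call__(self, x):
        return conv1d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _param((n_in, n_out), rng, np.sqrt(2.0 / n_in))
        self.b = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, train: bool):
        if train:
            y, m, v = batch_norm(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.astype(DTYPE))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * v.astype(DTYPE))
            return y
        x = _wrap(x)
        shape = [1] * x.data.ndim
        shape[1] = -1
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(shape)
        mean = self.running_mean.reshape(shape)
        scale = self.gamma.data.reshape(shape) * inv
        shift = self.beta.data.reshape(shape) - mean * scale
        return add(mul(x, Tensor(scale)), Tensor(shift))


class LSTM(Module):
    """Single LSTM layer over (N, T, D) inputs; returns (N, T, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(hidden)
        self.w_ih = _param((n_in, 4 * hidden), rng, scale)
        self.w_hh = _param((hidden, 4 * hidden), rng, scale)
        self.b = Tensor(np.zeros(4 * hidden, dtype=DTYPE), requires_grad=True)
        self.hidden = hidden

    def __call__(self, x):
        N, T, D = x.shape
        H = self.hidden
        h = Tensor(np.zeros((N, H), dtype=DTYPE))
        c = Tensor(np.zeros((N, H), dtype=DTYPE))
        outs = []
        for t in range(T):
            xt = getitem(x, (slice(None), t, slice(None)))
            gates = add(add(matmul(xt, self.w_ih), matmul(h, self.w_hh)), self.b)
            i = sigmoid(getitem(gates, (slice(None), slice(0, H))))
            f = sigmoid(getitem(gates, (slice(None), slice(H, 2 * H))))
            g = tanh(getitem(gates, (slice(None), slice(2 * H, 3 * H))))
            o = sigmoid(getitem(gates, (slice(None), slice(3 * H, 4 * H))))
            c = add(mul(f, c), mul(i, g))
            h = mul(o, tanh(c))
            outs.append(h)
        return stack(outs, axis=1)


def max_pool1d(x, pool: int) -> Tensor:
    """Non-overlapping max pooling along the last axis of (N, C, L)."""
    x = _wrap(x)
    N, C, L = x.shape
    Lc = (L // pool) * pool
    if Lc != L:
        x = getitem(x, (slice(None), slice(None), slice(0, Lc)))
    x = reshape(x, (N, C, Lc // pool, pool))
    return reduce_max(x, axis=3)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
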