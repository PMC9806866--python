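"""Minimal vectorized reverse-mode automatic differentiation over numpy.

The package trains small convolutional assemblies (a tiny dense backbone,
metadata gating blocks, a linear classifier) on desk-scale images.  This
module supplies exactly the tensor operations those assemblies need —
broadcast arithmetic, 2-D convolution via im2col, activations, pooling,
dropout and a fused softmax cross-entropy — together with ``Module``
parameter bookkeeping and SGD/Adam optimizers.  Everything is float64
numpy; no accelerator support is attempted.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Affine",
    "Conv2d",
    "SGD",
    "Adam",
    "add",
    "mul",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "concat",
    "mean",
    "reshape",
    "conv2d",
    "avg_pool2d",
    "global_avg_pool",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
    "uniform_init",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
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

    def zero_grad(self) -> None:
        self.grad = None

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A tensor registered as learnable inside a :class:`Module`."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------- ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def _bwd():
        g = out.grad
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out = _make(out_data, (a, b), _bwd)
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def _bwd():
        g = out.grad
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out = _make(out_data, (a, b), _bwd)
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def _bwd():
        g = out.grad
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out = _make(out_data, (a, b), _bwd)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def _bwd():
        x._accumulate(out.grad * mask)

    out = _make(np.where(mask, x.data, 0.0), (x,), _bwd)
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def _bwd():
        x._accumulate(out.grad * (1.0 - y * y))

    out = _make(y, (x,), _bwd)
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    y = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))

    def _bwd():
        x._accumulate(out.grad * y * (1.0 - y))

    out = _make(y, (x,), _bwd)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd():
        g = out.grad
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out = _make(out_data, tuple(tensors), _bwd)
    return out


def mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    count = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def _bwd():
        g = out.grad
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(sorted(a % x.data.ndim for a in axes)))
        x._accumulate(np.broadcast_to(g, x.data.shape) / count)

    out = _make(out_data, (x,), _bwd)
    return out


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    def _bwd():
        x._accumulate(out.grad.reshape(x.data.shape))

    out = _make(x.data.reshape(shape), (x,), _bwd)
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    # xp: padded input (n, c, hp, wp) -> columns (n, oh*ow, c*kh*kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw), oh, ow


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, oh, ow) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d6[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col + matmul."""
    n, c, h, wd = x.data.shape
    oc, ic, kh, kw = w.data.shape
    if ic != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {ic}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(oc, -1)
    out_data = (cols @ wmat.T).transpose(0, 2, 1).reshape(n, oc, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, oc, 1, 1)

    def _bwd():
        g = out.grad  # (n, oc, oh, ow)
        gcols = g.reshape(n, oc, oh * ow).transpose(0, 2, 1)  # (n, oh*ow, oc)
        w._accumulate(np.einsum("npo,npk->ok", gcols, cols).reshape(w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = gcols @ wmat  # (n, oh*ow, c*kh*kw)
        x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, padding, oh, ow))

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, _bwd)
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial dims {(h, w)} not divisible by {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def _bwd():
        g = out.grad / (k * k)
        x._accumulate(np.repeat(np.repeat(g, k, axis=2), k, axis=3))

    out = _make(out_data, (x,), _bwd)
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(n, c, h, w) -> (n, c) spatial mean."""
    return mean(x, axis=(2, 3))


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep  # inverted scaling

    def _bwd():
        x._accumulate(out.grad * mask)

    out = _make(x.data * mask, (x,), _bwd)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          sample_weight: np.ndarray | None = None) -> Tensor:
    """Mean multiclass cross-entropy of integer ``labels`` under ``logits``.

    With ``sample_weight`` the mean is weighted (weights normalized to sum 1).
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    if sample_weight is None:
        w = np.full(n, 1.0 / n)
    else:
        sample_weight = np.asarray(sample_weight, dtype=np.float64)
        w = sample_weight / sample_weight.sum()
    p = softmax(logits.data)
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    out_data = np.array((w * nll).sum())

    def _bwd():
        g = p.copy()
        g[np.arange(n), labels] -= 1.0
        logits._accumulate(out.grad * g * w[:, None])

    out = _make(out_data, (logits,), _bwd)
    return out


# ------------------------------------------------------------- modules

def uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Seeded uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    a = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-a, a, size=shape)


class Module:
    """Parameter container with recursive discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield key, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{key}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Affine(Module):
    """Fully connected layer y = x W + b with W of shape (in, out)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(uniform_init(rng, (n_in, n_out), n_in))
        self.bias = Parameter(uniform_init(rng, (n_out,), n_in))

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(uniform_init(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(uniform_init(rng, (c_out,), fan_in))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


# ----------------------------------------------------------- optimizers

class SGD:
    """Stochastic gradient descent with optional classical momentum."""

    def __init__(self, params: Sequence[Parameter], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
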