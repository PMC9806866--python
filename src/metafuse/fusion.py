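"""Metadata-fusion blocks: MetaNet, MetaBlock, MD-Net, and baselines.

All blocks condition convolutional image features ``X_img`` (shape
``(batch, k_img, h, w)``) on an encoded metadata vector ``X_meta`` (length
``d_meta``) at channel granularity:

* **MetaNet** — a two-layer subnetwork maps metadata through
  affine -> ReLU -> affine -> sigmoid to per-channel scales in (0,1) that
  multiplicatively reweight the feature channels.
* **MetaBlock** — two affine maps of the metadata, ``f_b = W_f^T x + w_0f``
  and ``g_b = W_g^T x + w_0g``, modulate the features through an LSTM-like
  pair of gates: ``sigma(tanh(f_b (*) X_img) + g_b)``, where ``(*)`` scales
  each channel and broadcasts over the spatial grid.  The output keeps the
  input's shape, every entry in (0,1).
* **MD-Net** — both blocks run on the same features; each output map is
  globally average-pooled to a ``k_img`` vector, projected to a common
  dimension ``d_fuse``, and the two streams are concatenated (summation is
  available as an option).
* **Concatenation / None** — the classical baselines: pooled image features
  with the raw metadata vector appended, or image features alone.

Each block exists once, as an autodiff :class:`~metafuse.nn.Module`; the
plain-array functions (:func:`metablock_forward`, :func:`metanet_forward`,
...) wrap the same computation for use outside a training graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Affine, Module, Parameter, Tensor

__all__ = [
    "MetaBlockParams", "MetaNetParams", "MDNetParams",
    "MetaBlock", "MetaNet", "MDNet", "ConcatFusion", "NoFusion",
    "f_b", "g_b", "tanh_gate", "sigmoid_gate",
    "metablock_forward", "metanet_forward", "mdnet_fuse", "concat_fuse",
    "make_fusion", "FUSION_VARIANTS",
]


# ------------------------------------------------------------ parameters

@dataclass
class MetaBlockParams:
    """Affine gate maps: ``W_f, W_g`` of shape ``(d_meta, k_img)``; biases ``(k_img,)``."""
    W_f: np.ndarray
    W_g: np.ndarray
    w_0f: np.ndarray
    w_0g: np.ndarray

    def __post_init__(self):
        self.W_f, self.W_g = np.atleast_2d(self.W_f), np.atleast_2d(self.W_g)
        self.w_0f, self.w_0g = np.atleast_1d(self.w_0f), np.atleast_1d(self.w_0g)
        d, k = self.W_f.shape
        if self.W_g.shape != (d, k) or self.w_0f.shape != (k,) or self.w_0g.shape != (k,):
            raise ValueError("MetaBlockParams: inconsistent shapes")

    @property
    def d_meta(self) -> int:
        return self.W_f.shape[0]

    @property
    def k_img(self) -> int:
        return self.W_f.shape[1]


@dataclass
class MetaNetParams:
    """Two-layer subnetwork: ``W1 (d_meta, hidden)``, ``W2 (hidden, k_img)`` with biases."""
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        self.W1, self.W2 = np.atleast_2d(self.W1), np.atleast_2d(self.W2)
        self.b1, self.b2 = np.atleast_1d(self.b1), np.atleast_1d(self.b2)
        if self.W1.shape[1] != self.b1.shape[0] or self.W2.shape[0] != self.b1.shape[0] \
                or self.W2.shape[1] != self.b2.shape[0]:
            raise ValueError("MetaNetParams: inconsistent shapes")

    @property
    def d_meta(self) -> int:
        return self.W1.shape[0]

    @property
    def k_img(self) -> int:
        return self.W2.shape[1]


@dataclass
class MDNetParams:
    metanet: MetaNetParams
    metablock: MetaBlockParams
    P_net: np.ndarray      # (k_img, d_fuse)
    bp_net: np.ndarray
    P_block: np.ndarray    # (k_img, d_fuse)
    bp_block: np.ndarray

    def __post_init__(self):
        self.P_net, self.P_block = np.atleast_2d(self.P_net), np.atleast_2d(self.P_block)
        self.bp_net, self.bp_block = np.atleast_1d(self.bp_net), np.atleast_1d(self.bp_block)
        if self.P_net.shape != self.P_block.shape:
            raise ValueError("MDNetParams: the two projections must target the same d_fuse")

    @property
    def d_fuse(self) -> int:
        return self.P_net.shape[1]


# ----------------------------------------------------------- shape utils

def _as_img4(X_img) -> tuple[np.ndarray, bool]:
    X = np.asarray(X_img, dtype=np.float64)
    if X.ndim == 3:
        return X[None], True
    if X.ndim != 4:
        raise ValueError(f"expected feature map of rank 3 or 4, got rank {X.ndim}")
    return X, False


def _as_meta2(X_meta, n: int) -> np.ndarray:
    M = np.asarray(X_meta, dtype=np.float64)
    if M.ndim == 1:
        M = np.broadcast_to(M, (n, M.shape[0])).copy()
    if M.ndim != 2 or M.shape[0] != n:
        raise ValueError(f"metadata batch shape {M.shape} incompatible with batch {n}")
    return M


def _check_channels(k_have: int, k_want: int, what: str) -> None:
    if k_have != k_want:
        raise ValueError(f"{what}: feature map has {k_have} channels, expected {k_want}")


# -------------------------------------------------------------- modules

class MetaBlock(Module):
    """Gated modulation ``sigma(tanh(f_b(x_meta) (*) X_img) + g_b(x_meta))``."""

    def __init__(self, d_meta: int, k_img: int, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W_f = Parameter(nn.uniform_init(rng, (d_meta, k_img), d_meta))
        self.w_0f = Parameter(nn.uniform_init(rng, (k_img,), d_meta))
        self.W_g = Parameter(nn.uniform_init(rng, (d_meta, k_img), d_meta))
        self.w_0g = Parameter(nn.uniform_init(rng, (k_img,), d_meta))
        self.d_meta, self.k_img = d_meta, k_img

    @classmethod
    def from_params(cls, p: MetaBlockParams) -> "MetaBlock":
        mod = cls(p.d_meta, p.k_img)
        mod.load_state_dict({"W_f": p.W_f, "w_0f": p.w_0f, "W_g": p.W_g, "w_0g": p.w_0g})
        return mod

    def forward(self, x_img: Tensor, x_meta: Tensor) -> Tensor:
        n, k = x_img.shape[0], x_img.shape[1]
        _check_channels(k, self.k_img, "MetaBlock")
        fmod = nn.matmul(x_meta, self.W_f) + self.w_0f      # (n, k)
        gmod = nn.matmul(x_meta, self.W_g) + self.w_0g
        fmod4 = nn.reshape(fmod, (n, k, 1, 1))
        gmod4 = nn.reshape(gmod, (n, k, 1, 1))
        return nn.sigmoid(nn.tanh(fmod4 * x_img) + gmod4)


class MetaNet(Module):
    """Multiplicative channel reweighting by sigmoid scales from metadata."""

    def __init__(self, d_meta: int, k_img: int, hidden: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = hidden if hidden is not None else d_meta
        self.layer1 = Affine(d_meta, hidden, rng)
        self.layer2 = Affine(hidden, k_img, rng)
        self.d_meta, self.k_img, self.hidden = d_meta, k_img, hidden

    @classmethod
    def from_params(cls, p: MetaNetParams) -> "MetaNet":
        mod = cls(p.d_meta, p.k_img, hidden=p.b1.shape[0])
        mod.load_state_dict({"layer1.weight": p.W1, "layer1.bias": p.b1,
                             "layer2.weight": p.W2, "layer2.bias": p.b2})
        return mod

    def channel_scales(self, x_meta: Tensor) -> Tensor:
        return nn.sigmoid(self.layer2(nn.relu(self.layer1(x_meta))))

    def forward(self, x_img: Tensor, x_meta: Tensor) -> Tensor:
        n, k = x_img.shape[0], x_img.shape[1]
        _check_channels(k, self.k_img, "MetaNet")
        s = self.channel_scales(x_meta)                     # (n, k) in (0,1)
        return nn.reshape(s, (n, k, 1, 1)) * x_img


class MDNet(Module):
    """MetaNet + MetaBlock run in parallel, pooled, projected, fused.

    ``mode`` is ``"concat"`` (default; output length ``2*d_fuse``) or
    ``"sum"`` (output length ``d_fuse``).
    """

    def __init__(self, d_meta: int, k_img: int, d_fuse: int | None = None,
                 hidden: int | None = None, mode: str = "concat",
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        if mode not in ("concat", "sum"):
            raise ValueError(f"MDNet: unknown fusion mode {mode!r}")
        d_fuse = d_fuse if d_fuse is not None else math.ceil(k_img / 2)
        self.metanet = MetaNet(d_meta, k_img, hidden=hidden, rng=rng)
        self.metablock = MetaBlock(d_meta, k_img, rng=rng)
        self.proj_net = Affine(k_img, d_fuse, rng)
        self.proj_block = Affine(k_img, d_fuse, rng)
        self.d_meta, self.k_img, self.d_fuse, self.mode = d_meta, k_img, d_fuse, mode

    @property
    def out_dim(self) -> int:
        return 2 * self.d_fuse if self.mode == "concat" else self.d_fuse

    @classmethod
    def from_params(cls, p: MDNetParams, mode: str = "concat") -> "MDNet":
        mod = cls(p.metablock.d_meta, p.metablock.k_img, d_fuse=p.d_fuse,
                  hidden=p.metanet.b1.shape[0], mode=mode)
        mod.metanet = MetaNet.from_params(p.metanet)
        mod.metablock = MetaBlock.from_params(p.metablock)
        mod.proj_net.load_state_dict({"weight": p.P_net, "bias": p.bp_net})
        mod.proj_block.load_state_dict({"weight": p.P_block, "bias": p.bp_block})
        return mod

    def forward(self, x_img: Tensor, x_meta: Tensor) -> Tensor:
        zn = self.proj_net(nn.global_avg_pool(self.metanet(x_img, x_meta)))
        zb = self.proj_block(nn.global_avg_pool(self.metablock(x_img, x_meta)))
        return nn.concat([zn, zb], axis=1) if self.mode == "concat" else zn + zb


class ConcatFusion(Module):
    """Baseline: pooled image features with the metadata vector appended."""

    def __init__(self, d_meta: int, k_img: int):
        self.d_meta, self.k_img = d_meta, k_img

    @property
    def out_dim(self) -> int:
        return self.k_img + self.d_meta

    def forward(self, x_img: Tensor, x_meta: Tensor) -> Tensor:
        _check_channels(x_img.shape[1], self.k_img, "ConcatFusion")
        return nn.concat([nn.global_avg_pool(x_img), x_meta], axis=1)


class NoFusion(Module):
    """Baseline: image features alone; metadata is ignored."""

    def __init__(self, d_meta: int, k_img: int):
        self.d_meta, self.k_img = d_meta, k_img

    @property
    def out_dim(self) -> int:
        return self.k_img

    def forward(self, x_img: Tensor, x_meta: Tensor) -> Tensor:
        _check_channels(x_img.shape[1], self.k_img, "NoFusion")
        return nn.global_avg_pool(x_img)


FUSION_VARIANTS = ("mdnet", "metanet", "metablock", "concat", "none")


def make_fusion(name: str, d_meta: int, k_img: int,
                rng: np.random.Generator | None = None, **kwargs) -> Module:
    """Instantiate a fusion block by its variant name.

    Standalone ``metanet``/``metablock`` blocks return feature maps; the
    assembly pools them before the classifier, so their effective
    ``out_dim`` is ``k_img`` (attached here for uniformity).
    """
    name = name.lower()
    if name == "mdnet":
        return MDNet(d_meta, k_img, rng=rng, **kwargs)
    if name == "metanet":
        mod = MetaNet(d_meta, k_img, rng=rng, **kwargs)
    elif name == "metablock":
        mod = MetaBlock(d_meta, k_img, rng=rng, **kwargs)
    elif name == "concat":
        return ConcatFusion(d_meta, k_img)
    elif name == "none":
        return NoFusion(d_meta, k_img)
    else:
        raise ValueError(f"unknown fusion variant {name!r}; choose from {FUSION_VARIANTS}")
    mod.out_dim = k_img
    return mod


# ------------------------------------------------- plain-array functions

def f_b(X_meta, params: MetaBlockParams) -> np.ndarray:
    """Tanh-gate modifier ``W_f^T x_meta + w_0f`` (per channel)."""
    X = np.asarray(X_meta, dtype=np.float64)
    if X.shape[-1] != params.d_meta:
        raise ValueError(f"f_b: metadata length {X.shape[-1]} != d_meta {params.d_meta}")
    return X @ params.W_f + params.w_0f


def g_b(X_meta, params: MetaBlockParams) -> np.ndarray:
    """Sigmoid-gate modifier ``W_g^T x_meta + w_0g`` (per channel)."""
    X = np.asarray(X_meta, dtype=np.float64)
    if X.shape[-1] != params.d_meta:
        raise ValueError(f"g_b: metadata length {X.shape[-1]} != d_meta {params.d_meta}")
    return X @ params.W_g + params.w_0g


def _bcast_mod(mod: np.ndarray, X: np.ndarray, what: str) -> np.ndarray:
    mod = np.asarray(mod, dtype=np.float64)
    k = X.shape[1]
    if mod.ndim == 1:
        if mod.shape[0] != k:
            raise ValueError(f"{what}: modifier length {mod.shape[0]} != k_img {k}")
        return mod.reshape(1, k, 1, 1)
    if mod.ndim == 2:
        if mod.shape != (X.shape[0], k):
            raise ValueError(f"{what}: modifier shape {mod.shape} != {(X.shape[0], k)}")
        return mod.reshape(X.shape[0], k, 1, 1)
    raise ValueError(f"{what}: modifier must be rank 1 or 2")


def tanh_gate(X_img, fmod) -> np.ndarray:
    """Scale each channel by its modifier, then elementwise tanh; range (-1, 1)."""
    X, squeeze = _as_img4(X_img)
    out = np.tanh(_bcast_mod(fmod, X, "tanh_gate") * X)
    return out[0] if squeeze else out


def sigmoid_gate(T, gmod) -> np.ndarray:
    """Shift each channel by its modifier, then the logistic map; range (0, 1)."""
    T4, squeeze = _as_img4(T)
    z = _bcast_mod(gmod, T4, "sigmoid_gate") + T4
    out = 1.0 / (1.0 + np.exp(-z))
    return out[0] if squeeze else out


def metablock_forward(X_img, X_meta, params: MetaBlockParams) -> np.ndarray:
    """Full MetaBlock: ``sigma(tanh(f_b (*) X_img) + g_b)``, shape-preserving."""
    X, squeeze = _as_img4(X_img)
    M = _as_meta2(X_meta, X.shape[0])
    out = MetaBlock.from_params(params)(Tensor(X), Tensor(M)).data
    return out[0] if squeeze else out


def metanet_forward(X_img, X_meta, params: MetaNetParams) -> np.ndarray:
    """Full MetaNet: sigmoid channel scales times the feature map."""
    X, squeeze = _as_img4(X_img)
    M = _as_meta2(X_meta, X.shape[0])
    out = MetaNet.from_params(params)(Tensor(X), Tensor(M)).data
    return out[0] if squeeze else out


def mdnet_fuse(X_img, X_meta, params: MDNetParams, mode: str = "concat") -> np.ndarray:
    """MD-Net fusion: pool both block outputs, project to d_fuse, fuse."""
    X, squeeze = _as_img4(X_img)
    M = _as_meta2(X_meta, X.shape[0])
    out = MDNet.from_params(params, mode=mode)(Tensor(X), Tensor(M)).data
    return out[0] if squeeze else out


def concat_fuse(X_img, X_meta) -> np.ndarray:
    """Baseline fusion: global-average-pooled features ++ metadata vector."""
    X, squeeze = _as_img4(X_img)
    M = _as_meta2(X_meta, X.shape[0])
    out = np.concatenate([X.mean(axis=(2, 3)), M], axis=1)
    return out[0] if squeeze else out
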