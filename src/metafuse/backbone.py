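"""Convolutional feature extractors with dense connectivity.

The fusion blocks attach to the pre-pooling feature map of a convolutional
backbone, so every extractor here maps ``(batch, 3, H, W)`` images to a
``(batch, k_img, h, w)`` map and declares its channel count ``k_img``.

Dense connectivity means layer ``l`` receives the channel-concatenation of
the block input and every preceding layer's output,
``X_l = H_l([X_0, X_1, ..., X_{l-1}])``, so a block with ``L`` layers of
growth ``g`` turns ``c`` input channels into ``c + L*g`` output channels.
Two extractors are provided: a tiny dense backbone sized for 32x32 test
images, and a generic multi-block dense architecture whose standard layer
configurations reproduce the channel arithmetic of the 121/169/201-layer
networks (e.g. 1664 channels for the 169-layer variant).  Full-scale
pretraining is out of scope; weights either load from a checkpoint through
:func:`load_pretrained` or initialize from a seeded scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Conv2d, Module, Tensor

__all__ = [
    "FeatureExtractor", "DenseBlock", "DenseBlockParams", "dense_block_forward",
    "TinyDenseBackbone", "DenseNetBackbone", "load_pretrained", "SUPPORTED_BACKBONES",
]


class FeatureExtractor(Module):
    """Contract: ``forward(images) -> FeatureMap`` with declared ``k_img``."""

    k_img: int
    name: str = "base"

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class _DenseLayer(Module):
    """H_l of a dense block: ReLU -> (optional 1x1 bottleneck) -> 3x3 conv."""

    def __init__(self, c_in: int, growth: int, rng: np.random.Generator,
                 bottleneck: bool = False):
        if bottleneck:
            self.reduce = Conv2d(c_in, 4 * growth, 1, rng)
            self.conv = Conv2d(4 * growth, growth, 3, rng, padding=1)
        else:
            self.reduce = None
            self.conv = Conv2d(c_in, growth, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(x)
        if self.reduce is not None:
            h = nn.relu(self.reduce(h))
        return self.conv(h)


class DenseBlock(Module):
    """``L`` densely connected layers, each adding ``growth`` channels."""

    def __init__(self, c_in: int, growth: int, num_layers: int,
                 rng: np.random.Generator | None = None, bottleneck: bool = False):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.growth, self.num_layers = c_in, growth, num_layers
        self.layers = [
            _DenseLayer(c_in + i * growth, growth, rng, bottleneck=bottleneck)
            for i in range(num_layers)
        ]

    @property
    def c_out(self) -> int:
        return self.c_in + self.num_layers * self.growth

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c_in:
            raise ValueError(f"DenseBlock: input has {x.shape[1]} channels, expected {self.c_in}")
        maps = [x]
        for layer in self.layers:
            maps.append(layer(nn.concat(maps, axis=1) if len(maps) > 1 else maps[0]))
        return nn.concat(maps, axis=1)


@dataclass
class DenseBlockParams:
    """Plain-array dense-block weights: one ``(conv weight, conv bias)`` pair per layer."""
    c_in: int
    growth: int
    kernels: list  # [(w: (growth, c_in + l*growth, kh, kw), b: (growth,)), ...]

    @property
    def num_layers(self) -> int:
        return len(self.kernels)


def dense_block_forward(X0: np.ndarray, params: DenseBlockParams) -> np.ndarray:
    """Run a dense block on a plain array; output channels = c_in + L*growth."""
    X0 = np.asarray(X0, dtype=np.float64)
    squeeze = X0.ndim == 3
    if squeeze:
        X0 = X0[None]
    if X0.shape[1] != params.c_in:
        raise ValueError(f"dense_block_forward: {X0.shape[1]} channels, expected {params.c_in}")
    rng = np.random.default_rng(0)
    block = DenseBlock(params.c_in, params.growth, params.num_layers, rng)
    state = {}
    for i, (w, b) in enumerate(params.kernels):
        state[f"layers.{i}.conv.weight"] = np.asarray(w, dtype=np.float64)
        state[f"layers.{i}.conv.bias"] = np.asarray(b, dtype=np.float64)
    block.load_state_dict(state)
    out = block(Tensor(X0)).data
    return out[0] if squeeze else out


class TinyDenseBackbone(FeatureExtractor):
    """Desk-scale dense extractor for small RGB images.

    A strided 3x3 stem plus 2x2 average pooling reduce a ``4m x 4m`` image
    to an ``m x m`` grid, then one dense block raises the channel count to
    ``k_img = stem_channels + num_layers * growth`` (16 by default).
    """

    name = "tiny-dense-test"

    def __init__(self, stem_channels: int = 8, growth: int = 4, num_layers: int = 2,
                 seed: int = 0, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.stem = Conv2d(3, stem_channels, 3, rng, stride=2, padding=1)
        self.block = DenseBlock(stem_channels, growth, num_layers, rng)
        self.k_img = self.block.c_out

    def forward(self, x: Tensor) -> Tensor:
        h = nn.avg_pool2d(nn.relu(self.stem(x)), 2)
        return self.block(h)


class _Transition(Module):
    """1x1 channel-halving conv + 2x2 average pool between dense blocks."""

    def __init__(self, c_in: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, c_in // 2, 1, rng)
        self.c_out = c_in // 2

    def forward(self, x: Tensor) -> Tensor:
        return nn.avg_pool2d(self.conv(nn.relu(x)), 2)


class DenseNetBackbone(FeatureExtractor):
    """Generic multi-block dense architecture (stem + blocks + transitions).

    ``block_config=(6, 12, 32, 32)`` with ``growth=32`` gives the standard
    169-layer variant and its 1664 pre-pooling channels.
    """

    def __init__(self, block_config: tuple[int, ...] = (6, 12, 32, 32),
                 growth: int = 32, stem_channels: int = 64, seed: int = 0,
                 name: str = "densenet", rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(seed)
        self.name = name
        self.stem = Conv2d(3, stem_channels, 7, rng, stride=2, padding=3)
        stages: list[Module] = []
        c = stem_channels
        for i, L in enumerate(block_config):
            stages.append(DenseBlock(c, growth, L, rng, bottleneck=True))
            c += L * growth
            if i < len(block_config) - 1:
                trans = _Transition(c, rng)
                stages.append(trans)
                c = trans.c_out
        self.stages = stages
        self.k_img = c

    def forward(self, x: Tensor) -> Tensor:
        h = nn.avg_pool2d(nn.relu(self.stem(x)), 2)
        for stage in self.stages:
            h = stage(h)
        return h


SUPPORTED_BACKBONES = {
    "tiny-dense-test": None,
    "densenet121": (6, 12, 24, 16),
    "densenet169": (6, 12, 32, 32),
    "densenet201": (6, 12, 48, 32),
}


def load_pretrained(name: str, weights_path: str | None = None, seed: int = 0,
                    **kwargs) -> FeatureExtractor:
    """Build a named extractor, optionally loading checkpointed weights.

    Without ``weights_path`` the extractor starts from seeded random
    initialization.  A weights file whose tensors do not match the named
    architecture raises ``ValueError``.
    """
    if name not in SUPPORTED_BACKBONES:
        raise ValueError(
            f"unknown backbone {name!r}; supported: {sorted(SUPPORTED_BACKBONES)}")
    if name == "tiny-dense-test":
        extractor: FeatureExtractor = TinyDenseBackbone(seed=seed, **kwargs)
    else:
        extractor = DenseNetBackbone(block_config=SUPPORTED_BACKBONES[name],
                                     seed=seed, name=name, **kwargs)
    if weights_path is not None:
        with np.load(weights_path) as npz:
            state = {k: npz[k] for k in npz.files}
        try:
            extractor.load_state_dict(state)
        except ValueError as e:
            raise ValueError(f"weights at {weights_path!r} do not match {name!r}: {e}") from None
    return extractor
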