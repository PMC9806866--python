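"""Training protocol: split, augmentation, plateau LR halving, early stop.

The harness reproduces a standard small-data fine-tuning recipe: batches
of 30, multiclass cross-entropy, a 3:1 train:test split (with a further
held-out validation fraction carved from the training portion), random
flip/brightness/contrast/saturation augmentation on training images only,
halving of the learning rate after 10 validation epochs without
improvement, early stopping after 15, and an epoch cap of 150.  Validation
performance is balanced accuracy throughout, and the parameters restored
at the end of a fit are those of the best validation epoch.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn
from .fusion import make_fusion
from .metrics import MetricsReport, compute_report
from .nn import Adam, Affine, Module, SGD, Tensor

__all__ = [
    "AugmentConfig", "TrainConfig", "TrainHistory", "Assembly",
    "split_dataset", "parse_ratio", "augment",
    "lr_schedule_step", "early_stop_check", "fit", "evaluate",
]


@dataclass
class AugmentConfig:
    """Probabilities/magnitudes of the stochastic training augmentations."""
    hflip: float = 0.5
    vflip: float = 0.5
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2

    def is_identity(self) -> bool:
        return not any(asdict(self).values())


@dataclass
class TrainConfig:
    batch_size: int = 30
    max_epochs: int = 150
    lr: float = 1e-3
    lr_patience: int = 10
    lr_factor: float = 0.5
    stop_patience: int = 15
    seed: int = 0
    split_ratio: str = "3:1"          # train:test
    val_fraction: float = 0.2         # of the training portion
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    optimizer: str = "adam"           # "adam" | "sgd"
    momentum: float = 0.9
    dropout: float = 0.5
    class_weighting: bool = False

    def __post_init__(self):
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if isinstance(self.augment, dict):
            self.augment = AugmentConfig(**self.augment)


@dataclass
class TrainHistory:
    """Per-epoch loss, validation balanced accuracy and learning rate."""
    loss: list = field(default_factory=list)
    val_bacc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def append(self, loss: float, val_bacc: float, lr: float) -> None:
        self.loss.append(float(loss))
        self.val_bacc.append(float(val_bacc))
        self.lr.append(float(lr))

    def __len__(self) -> int:
        return len(self.val_bacc)

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def parse_ratio(ratio) -> float:
    """Interpret a split ratio as the held-out test fraction.

    Accepts a float in (0, 1) or a string ``"train:test"`` (``"3:1"`` ->
    0.25).
    """
    if isinstance(ratio, str):
        try:
            a, b = (float(x) for x in ratio.split(":"))
        except ValueError:
            raise ValueError(f"cannot parse split ratio {ratio!r}") from None
        if a <= 0 or b <= 0:
            raise ValueError(f"split ratio parts must be positive, got {ratio!r}")
        frac = b / (a + b)
    else:
        frac = float(ratio)
    if not 0.0 < frac < 1.0:
        raise ValueError(f"test fraction must lie in (0, 1), got {frac}")
    return frac


def split_dataset(samples: Sequence, ratio="3:1", seed: int = 0,
                  stratify: bool = True, labels: Sequence | None = None):
    """Deterministic (seeded) train/test partition, stratified by default.

    ``samples`` may be any indexable sequence; when ``labels`` is omitted
    and the elements carry a ``label`` attribute it is used for
    stratification.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    frac = parse_ratio(ratio)
    if labels is None and stratify:
        labels = [getattr(s, "label") for s in samples]
    idx = np.arange(len(samples))
    train_idx, test_idx = train_test_split(
        idx, test_size=frac, random_state=seed,
        stratify=np.asarray(labels) if stratify else None, shuffle=True)
    take = lambda ii: [samples[i] for i in ii] if isinstance(samples, list) \
        else samples[np.asarray(ii)]
    return take(sorted(train_idx)), take(sorted(test_idx))


def augment(image: np.ndarray, rng: np.random.Generator,
            config: AugmentConfig | None = None) -> np.ndarray:
    """Randomly flip and jitter one ``(3, H, W)`` float image in [0, 1].

    Brightness/contrast/saturation factors are drawn uniformly from
    ``1 +- magnitude``; output dimensions always equal input dimensions.
    All-zero settings return the input unchanged (and draw nothing from
    ``rng``, so the operation is exactly the identity).
    """
    cfg = config if config is not None else AugmentConfig()
    if cfg.is_identity():
        return image
    img = image
    if cfg.hflip and rng.random() < cfg.hflip:
        img = img[:, :, ::-1]
    if cfg.vflip and rng.random() < cfg.vflip:
        img = img[:, ::-1, :]
    img = np.ascontiguousarray(img, dtype=np.float64)
    if cfg.brightness:
        img = img * rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    if cfg.contrast:
        f = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
        mean = img.mean()
        img = (img - mean) * f + mean
    if cfg.saturation:
        f = rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
        gray = img.mean(axis=0, keepdims=True)
        img = gray + (img - gray) * f
    return np.clip(img, 0.0, 1.0)


def _epochs_since_improvement(val_metric: Sequence[float], start: int = 0) -> int:
    """Epochs elapsed after the last strict improvement (scanning from start)."""
    best = -np.inf
    last_improve = start - 1
    for i in range(len(val_metric)):
        if val_metric[i] > best:
            best = val_metric[i]
            last_improve = i
    return len(val_metric) - 1 - last_improve


def lr_schedule_step(history: TrainHistory, current_lr: float,
                     config: TrainConfig) -> float:
    """Halve the learning rate after ``lr_patience`` non-improving epochs.

    An epoch improves when its validation balanced accuracy strictly
    exceeds the best seen so far.  The non-improvement count restarts at
    each reduction (identified by drops in the recorded LR trace), so one
    plateau triggers exactly one halving.
    """
    if len(history) == 0:
        raise ValueError("lr_schedule_step: history is empty")
    lrs = history.lr
    last_reduction = -1
    for i in range(1, len(lrs)):
        if lrs[i] < lrs[i - 1]:
            last_reduction = i
    best = -np.inf
    last_improve = -1
    for i, v in enumerate(history.val_bacc):
        if v > best:
            best = v
            last_improve = i
    anchor = max(last_improve, last_reduction)
    if len(history) - 1 - anchor >= config.lr_patience:
        return current_lr * config.lr_factor
    return current_lr


def early_stop_check(history: TrainHistory, config: TrainConfig) -> bool:
    """True when validation has not improved for ``stop_patience`` epochs."""
    if len(history) == 0:
        raise ValueError("early_stop_check: history is empty")
    return _epochs_since_improvement(history.val_bacc) >= config.stop_patience


class Assembly(Module):
    """Backbone + fusion block + dropout + linear classifier."""

    def __init__(self, backbone, fusion, n_classes: int,
                 rng: np.random.Generator | None = None, dropout: float = 0.5):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.backbone = backbone
        self.fusion = fusion
        fused_dim = fusion.out_dim
        self.classifier = Affine(fused_dim, n_classes, rng)
        self.n_classes = n_classes
        self.dropout_rate = dropout

    def forward(self, x_img: Tensor, x_meta: Tensor,
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        h = self.backbone(x_img)
        z = self.fusion(h, x_meta)
        if len(z.shape) == 4:  # standalone gating blocks return feature maps
            z = nn.global_avg_pool(z)
        if training and rng is not None:
            z = nn.dropout(z, self.dropout_rate, rng, training=True)
        return self.classifier(z)

    def predict_proba(self, images: np.ndarray, meta: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Deterministic forward pass (no augmentation, no dropout)."""
        out = []
        for lo in range(0, len(images), batch_size):
            logits = self.forward(Tensor(images[lo:lo + batch_size]),
                                  Tensor(meta[lo:lo + batch_size]))
            out.append(nn.softmax(logits.data))
        return np.concatenate(out, axis=0)


def _make_optimizer(assembly: Assembly, config: TrainConfig):
    params = assembly.parameters()
    if config.optimizer == "adam":
        return Adam(params, lr=config.lr)
    if config.optimizer == "sgd":
        return SGD(params, lr=config.lr, momentum=config.momentum)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def _val_bacc(assembly: Assembly, images, meta, labels, classes) -> float:
    proba = assembly.predict_proba(images, meta)
    preds = proba.argmax(axis=1)
    report = compute_report([classes[i] for i in labels],
                            [classes[i] for i in preds], classes)
    return report.bacc


def fit(assembly: Assembly, train_data, val_data, config: TrainConfig,
        verbose: bool = False, log_file=None):
    """Minimize multiclass cross-entropy over the assembly.

    ``train_data``/``val_data`` are ``(images (n,3,H,W) in [0,1], meta
    (n,d_meta), labels int (n,))`` triples.  Augmentation applies to
    training batches only; validation balanced accuracy drives both the
    plateau LR halving and early stopping; the returned parameters are the
    best-validation snapshot.

    Returns ``(best_state_dict, TrainHistory)``.
    """
    X, M, y = (np.asarray(a) for a in train_data)
    Xv, Mv, yv = (np.asarray(a) for a in val_data)
    if len(X) == 0:
        raise ValueError("fit: empty training set")
    classes = tuple(range(assembly.n_classes))
    history = TrainHistory()
    if config.max_epochs == 0:
        return assembly.state_dict(), history

    rng = np.random.default_rng(config.seed)
    shuffle_rng = np.random.default_rng(rng.integers(2**31))
    aug_rng = np.random.default_rng(rng.integers(2**31))
    drop_rng = np.random.default_rng(rng.integers(2**31))
    opt = _make_optimizer(assembly, config)
    lr = config.lr
    sample_weight = None
    if config.class_weighting:
        freq = np.bincount(y, minlength=assembly.n_classes).astype(float)
        w_class = np.where(freq > 0, len(y) / np.maximum(freq, 1) / assembly.n_classes, 0.0)
        sample_weight = w_class[y]

    best_state = assembly.state_dict()
    best_bacc = -np.inf
    for epoch in range(config.max_epochs):
        perm = shuffle_rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), config.batch_size):
            idx = perm[lo:lo + config.batch_size]
            xb = X[idx]
            if config.augment is not None and not config.augment.is_identity():
                xb = np.stack([augment(im, aug_rng, config.augment) for im in xb])
            logits = assembly.forward(Tensor(xb), Tensor(M[idx]),
                                      rng=drop_rng, training=True)
            loss = nn.softmax_cross_entropy(
                logits, y[idx],
                sample_weight=None if sample_weight is None else sample_weight[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"fit aborted: non-finite loss at epoch {epoch} "
                    f"(lr={lr:g}); inspect inputs or lower the learning rate")
            assembly.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        vb = _val_bacc(assembly, Xv, Mv, yv, classes)
        history.append(np.mean(losses), vb, lr)
        if vb > best_bacc:
            best_bacc = vb
            best_state = assembly.state_dict()
            history.best_epoch = epoch
        record = {"epoch": epoch, "loss": float(np.mean(losses)),
                  "val_bacc": vb, "lr": lr}
        if verbose:
            import sys
            print(json.dumps(record), file=sys.stderr)
        if log_file is not None:
            log_file.write(json.dumps(record) + "\n")
        new_lr = lr_schedule_step(history, lr, config)
        if new_lr < lr:
            lr = new_lr
            opt.lr = lr
        if early_stop_check(history, config):
            history.stopped_epoch = epoch
            break
    assembly.load_state_dict(best_state)
    return best_state, history


def evaluate(assembly: Assembly, test_data, classes=None) -> MetricsReport:
    """Deterministic evaluation of a trained assembly on held-out data."""
    X, M, y = (np.asarray(a) for a in test_data)
    if len(X) == 0:
        raise ValueError("evaluate: empty test set")
    if classes is None:
        classes = tuple(range(assembly.n_classes))
    proba = assembly.predict_proba(X, M)
    preds = proba.argmax(axis=1)
    return compute_report([classes[i] for i in y], [classes[i] for i in preds],
                          classes, class_scores=proba)
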