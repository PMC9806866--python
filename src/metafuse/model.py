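"""Model/Results interface over the fusion assemblies.

:class:`MetaFusionClassifier` is constructed from data (images, metadata
records, labels), assembles backbone + fusion block + classifier, and
``fit()`` returns a :class:`MetaFusionResults` carrying the trained
parameters, the training history and evaluation helpers — the same
model-object idiom statsmodels uses, applied to a trained classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .backbone import load_pretrained
from .encoding import MetadataSchema, build_schema, encode_batch
from .fusion import make_fusion
from .metrics import MetricsReport
from .training import Assembly, TrainConfig, TrainHistory, evaluate, fit, split_dataset

__all__ = ["MetaFusionClassifier", "MetaFusionResults", "load_results"]


class MetaFusionClassifier:
    """A metadata-fused lesion classifier specified by data plus an assembly.

    Parameters
    ----------
    images
        ``(n, 3, H, W)`` float array in [0, 1].
    records
        Metadata records, one field->value map per image.
    labels
        Class labels (any hashable); the sorted unique values define the
        class order.
    fusion
        One of ``"mdnet"``, ``"metanet"``, ``"metablock"``, ``"concat"``,
        ``"none"``.
    schema
        Optional pre-built :class:`MetadataSchema`; built from ``records``
        (deterministically) when omitted.
    """

    def __init__(self, images, records, labels, fusion: str = "mdnet",
                 backbone: str = "tiny-dense-test", schema: MetadataSchema | None = None,
                 config: TrainConfig | None = None, backbone_kwargs: dict | None = None,
                 fusion_kwargs: dict | None = None):
        self.images = np.asarray(images, dtype=np.float64)
        if self.images.ndim != 4 or self.images.shape[1] != 3:
            raise ValueError("images must have shape (n, 3, H, W)")
        if not (len(records) == len(labels) == len(self.images)):
            raise ValueError("images, records and labels must have equal length")
        self.records = list(records)
        self.schema = schema if schema is not None else build_schema(self.records)
        self.meta = encode_batch(self.records, self.schema)
        self.classes = tuple(sorted(set(labels)))
        index = {c: i for i, c in enumerate(self.classes)}
        self.y = np.array([index[l] for l in labels])
        self.fusion_name = fusion
        self.backbone_name = backbone
        self.backbone_kwargs = dict(backbone_kwargs or {})
        self.fusion_kwargs = dict(fusion_kwargs or {})
        self.config = config if config is not None else TrainConfig()

    @classmethod
    def from_directory(cls, root, image_size: int | None = None, **kwargs):
        """Build from an image-folder + metadata.csv layout."""
        from .data import load_dataset
        images, records, labels = load_dataset(root, image_size=image_size)
        return cls(images, records, labels, **kwargs)

    def build_assembly(self, seed: int | None = None) -> Assembly:
        seed = self.config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        backbone = load_pretrained(self.backbone_name, seed=int(rng.integers(2**31)),
                                   **self.backbone_kwargs)
        fusion = make_fusion(self.fusion_name, self.schema.d_meta, backbone.k_img,
                             rng=np.random.default_rng(int(rng.integers(2**31))),
                             **self.fusion_kwargs)
        return Assembly(backbone, fusion, len(self.classes),
                        rng=np.random.default_rng(int(rng.integers(2**31))),
                        dropout=self.config.dropout)

    def fit(self, config: TrainConfig | None = None, verbose: bool = False,
            log_file=None) -> "MetaFusionResults":
        """Train on an internal train/validation split and return results."""
        cfg = config if config is not None else self.config
        idx = np.arange(len(self.y))
        if cfg.val_fraction > 0:
            tr_idx, va_idx = split_dataset(idx, ratio=cfg.val_fraction, seed=cfg.seed,
                                           stratify=True, labels=self.y)
        else:
            tr_idx, va_idx = idx, idx
        assembly = self.build_assembly(seed=cfg.seed)
        train = (self.images[tr_idx], self.meta[tr_idx], self.y[tr_idx])
        val = (self.images[va_idx], self.meta[va_idx], self.y[va_idx])
        state, history = fit(assembly, train, val, cfg, verbose=verbose,
                             log_file=log_file)
        return MetaFusionResults(self, assembly, history, cfg)


class MetaFusionResults:
    """Trained parameters, history and evaluation for a fitted classifier."""

    def __init__(self, model: MetaFusionClassifier, assembly: Assembly,
                 history: TrainHistory, config: TrainConfig):
        self.model = model
        self.assembly = assembly
        self.history = history
        self.config = config

    # ------------------------------------------------------- inference
    def _encode(self, records) -> np.ndarray:
        return encode_batch(list(records), self.model.schema)

    def predict_proba(self, images, records) -> np.ndarray:
        return self.assembly.predict_proba(np.asarray(images, dtype=np.float64),
                                           self._encode(records))

    def predict(self, images, records) -> list:
        proba = self.predict_proba(images, records)
        return [self.model.classes[i] for i in proba.argmax(axis=1)]

    def evaluate(self, images, records, labels) -> MetricsReport:
        index = {c: i for i, c in enumerate(self.model.classes)}
        y = np.array([index[l] for l in labels])
        return evaluate(self.assembly,
                        (np.asarray(images, dtype=np.float64), self._encode(records), y),
                        classes=self.model.classes)

    # --------------------------------------------------------- reports
    def summary(self) -> str:
        m = self.model
        n_params = sum(p.data.size for p in self.assembly.parameters())
        lines = [
            "Metadata-fusion classifier results",
            "=" * 42,
            f"{'fusion block':<22}{m.fusion_name}",
            f"{'backbone':<22}{m.backbone_name} (k_img={self.assembly.backbone.k_img})",
            f"{'metadata dim':<22}{m.schema.d_meta}",
            f"{'classes':<22}{len(m.classes)}",
            f"{'parameters':<22}{n_params}",
            f"{'optimizer':<22}{self.config.optimizer} (lr0={self.config.lr:g})",
            f"{'epochs run':<22}{len(self.history)}",
            f"{'best epoch':<22}{self.history.best_epoch}",
            f"{'stopped epoch':<22}{self.history.stopped_epoch}",
        ]
        if len(self.history):
            lines.append(f"{'best val BACC':<22}{max(self.history.val_bacc):.4f}")
            lines.append(f"{'final lr':<22}{self.history.lr[-1]:g}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(len(self.history))
        ax.plot(epochs, self.history.loss, label="train loss")
        ax.plot(epochs, self.history.val_bacc, label="val BACC")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    # ----------------------------------------------------- persistence
    def save(self, path) -> Path:
        """Write a single ``.npz`` checkpoint plus a JSON manifest."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_name(path.name + ".npz")
        state = self.assembly.state_dict()
        np.savez(path, **state)
        d_fuse = getattr(self.assembly.fusion, "d_fuse", None)
        hidden = getattr(getattr(self.assembly.fusion, "metanet", self.assembly.fusion),
                         "hidden", None)
        manifest = {
            "fusion": self.model.fusion_name,
            "backbone": self.model.backbone_name,
            "backbone_kwargs": self.model.backbone_kwargs,
            "fusion_kwargs": self.model.fusion_kwargs,
            "d_meta": self.model.schema.d_meta,
            "k_img": self.assembly.backbone.k_img,
            "d_fuse": d_fuse,
            "hidden": hidden,
            "schema_hash": self.model.schema.digest(),
            "schema": json.loads(self.model.schema.to_json()),
            "classes": list(self.model.classes),
            "config": _config_dict(self.config),
            "history": json.loads(self.history.to_json()),
        }
        manifest_path = Path(str(path) + ".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2))
        return path


def _config_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


def load_results(checkpoint_path) -> tuple[Assembly, dict, MetadataSchema]:
    """Rebuild a trained assembly from ``save()`` output.

    Returns ``(assembly, manifest, schema)``; the manifest carries classes
    and training config for downstream evaluation.
    """
    checkpoint_path = Path(checkpoint_path)
    if checkpoint_path.suffix != ".npz":
        checkpoint_path = checkpoint_path.with_name(checkpoint_path.name + ".npz")
    manifest = json.loads(Path(str(checkpoint_path) + ".manifest.json").read_text())
    schema = MetadataSchema.from_json(json.dumps(manifest["schema"]))
    rng = np.random.default_rng(0)
    backbone = load_pretrained(manifest["backbone"], **manifest["backbone_kwargs"])
    fusion = make_fusion(manifest["fusion"], schema.d_meta, backbone.k_img,
                         rng=rng, **manifest["fusion_kwargs"])
    assembly = Assembly(backbone, fusion, len(manifest["classes"]), rng=rng,
                        dropout=manifest["config"].get("dropout", 0.5))
    with np.load(checkpoint_path) as npz:
        state = {k: npz[k] for k in npz.files}
    assembly.load_state_dict(state)
    return assembly, manifest, schema
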