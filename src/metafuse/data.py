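"""Reader for the image-folder + metadata-CSV dataset layout.

Expected layout (the same one :func:`metafuse.synthetic.write_dataset`
produces, mirroring how public lesion collections ship)::

    <root>/images/<img_id>.png
    <root>/metadata.csv    # columns: img_id, diagnostic, <metadata fields...>
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["load_dataset", "load_image", "records_from_frame"]


def load_image(path, size: int | None = None) -> np.ndarray:
    """Read an RGB image to a ``(3, H, W)`` float array in [0, 1]."""
    img = Image.open(path).convert("RGB")
    if size is not None:
        img = img.resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64).transpose(2, 0, 1) / 255.0


def records_from_frame(df: pd.DataFrame, id_col: str = "img_id",
                       label_col: str = "diagnostic") -> list[dict]:
    """Metadata records (field -> value maps) from a table, NaN -> missing."""
    meta_cols = [c for c in df.columns if c not in (id_col, label_col)]
    records = []
    for _, row in df.iterrows():
        rec = {}
        for c in meta_cols:
            v = row[c]
            if pd.isna(v):
                continue
            rec[c] = str(v)
        records.append(rec)
    return records


def load_dataset(root, id_col: str = "img_id", label_col: str = "diagnostic",
                 image_size: int | None = None):
    """Load a dataset directory.

    Returns ``(images (n,3,H,W) float in [0,1], records list of dicts,
    labels list)``, ordered as in the CSV.
    """
    root = Path(root)
    csv_path = root / "metadata.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no metadata.csv under {root}")
    df = pd.read_csv(csv_path)
    for col in (id_col, label_col):
        if col not in df.columns:
            raise ValueError(f"metadata.csv lacks required column {col!r}")
    images = np.stack([
        load_image(root / "images" / f"{img_id}.png", size=image_size)
        for img_id in df[id_col]
    ])
    records = records_from_frame(df, id_col=id_col, label_col=label_col)
    labels = df[label_col].tolist()
    return images, records, labels
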