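"""One-hot encoding of clinical metadata records.

Clinical attributes accompanying lesion images (sex, age band, anatomical
region, boolean symptoms ...) are categorical and unordered, so before they
can condition a convolutional model they are expanded into a fixed-length
binary vector: each field occupies a contiguous block with one bit per
category and exactly one bit set.  The block for a field missing from a
record is all zeros — a neutral code that keeps the encoded dimension
fixed.  Field and category order are deterministic (lexicographic unless
explicitly supplied), so the same schema is rebuilt bit-for-bit from the
same data in any run.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MetadataSchema",
    "build_schema",
    "encode_record",
    "encode_batch",
    "decode_vector",
    "bin_age",
]

Record = Mapping[str, object]


@dataclass(frozen=True)
class MetadataSchema:
    """Ordered categorical fields and their one-hot layout.

    Attributes
    ----------
    fields
        Ordered ``(field name, ordered category tuple)`` pairs.
    """

    fields: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def d_meta(self) -> int:
        """Total encoded dimension: the sum of per-field category counts."""
        return sum(len(cats) for _, cats in self.fields)

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.fields)

    def block_slices(self) -> dict[str, slice]:
        """Map each field to its slice of the encoded vector."""
        out, lo = {}, 0
        for name, cats in self.fields:
            out[name] = slice(lo, lo + len(cats))
            lo += len(cats)
        return out

    def to_json(self) -> str:
        return json.dumps({"fields": [[n, list(c)] for n, c in self.fields]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetadataSchema":
        obj = json.loads(text)
        return cls(tuple((n, tuple(c)) for n, c in obj["fields"]))

    def digest(self) -> str:
        """Stable hash identifying the schema inside checkpoint manifests."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _norm(value: object) -> str:
    return str(value)


def build_schema(records: Sequence[Record],
                 field_order: Sequence[str] | None = None,
                 category_orders: Mapping[str, Sequence[str]] | None = None,
                 ) -> MetadataSchema:
    """Enumerate every observed category per field into a deterministic schema.

    Parameters
    ----------
    records
        Non-empty sequence of field -> value maps; a field absent from a
        record is treated as missing for that record.
    field_order
        Explicit field ordering; defaults to lexicographic over the union
        of observed field names.
    category_orders
        Explicit per-field category orderings (e.g. ``{"sex": ["male",
        "female"]}``); fields not listed default to lexicographic order.
    """
    if not records:
        raise ValueError("build_schema: need at least one record")
    observed: dict[str, set[str]] = {}
    for rec in records:
        for k, v in rec.items():
            if v is None:
                continue
            observed.setdefault(k, set()).add(_norm(v))
    if not observed:
        raise ValueError("build_schema: no field has any observed category")
    if field_order is None:
        field_order = sorted(observed)
    else:
        unknown = set(field_order) - set(observed)
        if unknown:
            raise ValueError(f"build_schema: fields never observed: {sorted(unknown)}")
    fields = []
    for name in field_order:
        cats = observed.get(name, set())
        if not cats:
            raise ValueError(f"build_schema: field {name!r} has no observed categories")
        if category_orders and name in category_orders:
            order = [str(c) for c in category_orders[name]]
            missing = cats - set(order)
            if missing:
                raise ValueError(
                    f"build_schema: explicit order for {name!r} omits {sorted(missing)}")
            cats_ordered = tuple(order)
        else:
            cats_ordered = tuple(sorted(cats))
        fields.append((name, cats_ordered))
    return MetadataSchema(tuple(fields))


def encode_record(record: Record, schema: MetadataSchema) -> np.ndarray:
    """One-hot encode a single record into a length-``d_meta`` vector.

    Each present field sets exactly one bit in its block; a missing field
    (absent key or ``None`` value) leaves its block all-zero.  An unknown
    category raises ``ValueError`` naming the field and value.
    """
    known = set(schema.field_names)
    unknown_fields = {k for k, v in record.items() if v is not None} - known
    if unknown_fields:
        raise ValueError(f"encode_record: fields not in schema: {sorted(unknown_fields)}")
    vec = np.zeros(schema.d_meta)
    lo = 0
    for name, cats in schema.fields:
        value = record.get(name)
        if value is not None:
            v = _norm(value)
            try:
                idx = cats.index(v)
            except ValueError:
                raise ValueError(
                    f"encode_record: unknown category {v!r} for field {name!r}; "
                    f"known: {list(cats)}") from None
            vec[lo + idx] = 1.0
        lo += len(cats)
    return vec


def encode_batch(records: Sequence[Record], schema: MetadataSchema) -> np.ndarray:
    """Encode records row-wise into an ``(n, d_meta)`` matrix."""
    out = np.zeros((len(records), schema.d_meta))
    for i, rec in enumerate(records):
        try:
            out[i] = encode_record(rec, schema)
        except ValueError as e:
            raise ValueError(f"row {i}: {e}") from None
    return out


def decode_vector(vec: np.ndarray, schema: MetadataSchema) -> dict[str, str | None]:
    """Invert one-hot encoding: argmax per block, ``None`` for all-zero blocks."""
    vec = np.asarray(vec)
    if vec.shape != (schema.d_meta,):
        raise ValueError(f"decode_vector: expected shape ({schema.d_meta},), got {vec.shape}")
    out: dict[str, str | None] = {}
    lo = 0
    for name, cats in schema.fields:
        block = vec[lo:lo + len(cats)]
        out[name] = None if not block.any() else cats[int(block.argmax())]
        lo += len(cats)
    return out


def bin_age(age: float, edges: Sequence[float]) -> str:
    """Assign a continuous age to a half-open decile-style band.

    ``edges`` are interior cut points; ``bin_age(37, [30, 60])`` -> ``"30-60"``.
    Bands are labelled ``"<lo"``, ``"lo-hi"`` and ``">=hi"`` so the result is
    an ordinary categorical value for :func:`build_schema`.
    """
    edges = sorted(edges)
    if not edges:
        raise ValueError("bin_age: need at least one edge")
    if age < edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= age < hi:
            return f"{lo:g}-{hi:g}"
    return f">={edges[-1]:g}"
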