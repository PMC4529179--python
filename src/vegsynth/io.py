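"""Pattern serialization: CSV and JSON round trips, scene-placement export.

CSV files carry the region in a comment header line::

    # region: x_min y_min x_max y_max
    id,x,y,type_id[,dbh,height,crown_width]
    ...

JSON files are an object ``{"region": {...}, "elements": [...]}``; the shape
is described by :data:`PATTERN_SCHEMA` and checked structurally on read.
Files without region metadata fall back to the elements' bounding box.

:func:`export_scene` writes a flat placement table consumable by external 3-D
scene builders: one row per plant with its position, species and a
``model_scale`` column — proportional to the tree height when heights are
present, otherwise 1 plus a seeded uniform disturbance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pattern import ATTRIBUTE_COLUMNS, Region, VectorPattern

__all__ = ["read_pattern", "write_pattern", "export_scene", "PATTERN_SCHEMA"]

#: Structural schema of the JSON pattern format (JSON-Schema style, checked
#: by the lightweight validator below).
PATTERN_SCHEMA = {
    "type": "object",
    "required": ["region", "elements"],
    "properties": {
        "region": {
            "type": "object",
            "required": ["x_min", "y_min", "x_max", "y_max"],
            "properties": {
                k: {"type": "number"}
                for k in ("x_min", "y_min", "x_max", "y_max")
            },
        },
        "elements": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id", "x", "y", "type_id"],
                "properties": {
                    "id": {"type": "integer"},
                    "x": {"type": "number"},
                    "y": {"type": "number"},
                    "type_id": {"type": "integer"},
                    "dbh": {"type": ["number", "null"]},
                    "height": {"type": ["number", "null"]},
                    "crown_width": {"type": ["number", "null"]},
                },
            },
        },
    },
}


def validate_pattern_json(doc: object) -> None:
    """Structural check of a decoded pattern document against the schema."""
    if not isinstance(doc, dict):
        raise ValueError("pattern JSON must be an object")
    for key in PATTERN_SCHEMA["required"]:
        if key not in doc:
            raise ValueError(f"pattern JSON missing required key {key!r}")
    reg = doc["region"]
    if not isinstance(reg, dict) or any(
        k not in reg for k in ("x_min", "y_min", "x_max", "y_max")
    ):
        raise ValueError("region must carry x_min, y_min, x_max, y_max")
    if not isinstance(doc["elements"], list):
        raise ValueError("elements must be an array")
    for i, el in enumerate(doc["elements"]):
        for k in ("id", "x", "y", "type_id"):
            if k not in el:
                raise ValueError(f"element {i} missing required field {k!r}")


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format:
        return format.lower()
    suffix = path.suffix.lower().lstrip(".")
    return suffix if suffix in ("csv", "json") else "csv"


def read_pattern(path, format: Optional[str] = None) -> VectorPattern:
    """Load a pattern from CSV or JSON (inferred from the extension).

    Required columns/fields: ``x, y, type_id``; ``id`` is assigned from the
    row order when absent; DBH/height/crown width are optional. The region
    comes from the header metadata, else from the bounding box.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = json.loads(path.read_text())
        validate_pattern_json(doc)
        reg = doc["region"]
        region = Region(reg["x_min"], reg["y_min"], reg["x_max"], reg["y_max"])
        df = pd.DataFrame(doc["elements"])
    elif fmt == "csv":
        region = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "region" in first:
            vals = first.split(":", 1)[1].replace(",", " ").split()
            region = Region(*(float(v) for v in vals))
        df = pd.read_csv(path, comment="#")
    else:
        raise ValueError(f"unknown pattern format {fmt!r}")

    missing = [c for c in ("x", "y", "type_id") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at row {row}"
            )
        df[col] = pd.to_numeric(df[col])
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df), dtype=np.int64))
    keep = ["id", "x", "y", "type_id"] + [
        c for c in ATTRIBUTE_COLUMNS if c in df.columns
    ]
    df = df[keep]
    if region is None:
        if len(df) == 0:
            raise ValueError("cannot infer a region from an empty pattern")
        region = Region(
            float(df["x"].min()), float(df["y"].min()),
            float(df["x"].max() + np.finfo(float).eps),
            float(df["y"].max() + np.finfo(float).eps),
        )
    return VectorPattern(df, region)


def write_pattern(
    pattern: VectorPattern, path, format: Optional[str] = None
) -> Path:
    """Lossless serialization (region metadata, attributes, full precision)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "region": dict(
                zip(("x_min", "y_min", "x_max", "y_max"),
                    pattern.region.as_tuple())
            ),
            "elements": [
                {
                    "id": e.id,
                    "x": e.x,
                    "y": e.y,
                    "type_id": e.type_id,
                    **{
                        k: getattr(e, k)
                        for k in ATTRIBUTE_COLUMNS
                        if pattern.has_attributes
                    },
                }
                for e in pattern
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif fmt == "csv":
        r = pattern.region
        with open(path, "w") as fh:
            fh.write(f"# region: {r.x_min!r} {r.y_min!r} {r.x_max!r} {r.y_max!r}\n")
            pattern.df.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown pattern format {fmt!r}")
    return path


def export_scene(
    pattern: VectorPattern,
    path,
    scale_jitter: float = 0.2,
    seed: int = 0,
) -> Path:
    """Write the flat placement table for 3-D scene construction.

    Columns: x, y, type_id, dbh, height, crown_width, model_scale. When
    heights are present, ``model_scale = height / mean(height)``; otherwise
    each scale is ``1 + U(-scale_jitter, scale_jitter)``, seeded.
    """
    path = Path(path)
    df = pattern.df.copy()
    for col in ATTRIBUTE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    heights = df["height"].to_numpy()
    if np.isfinite(heights).any() and np.nanmean(heights) > 0:
        scale = heights / np.nanmean(heights)
        # elements without a height fall back to the average model size
        scale = np.where(np.isfinite(scale), scale, 1.0)
    else:
        rng = np.random.default_rng(seed)
        scale = 1.0 + rng.uniform(-scale_jitter, scale_jitter, len(df))
    df["model_scale"] = scale
    df[["x", "y", "type_id", "dbh", "height", "crown_width", "model_scale"]].to_csv(
        path, index=False, float_format="%.17g"
    )
    return path
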