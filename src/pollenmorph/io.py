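"""Frozen on-disk formats.

- Feature tables: CSV with columns ``grain_id, taxon, view`` then the 7 core
  feature names verbatim and ``texture_01..texture_43`` (schema v1, strict:
  unknown or missing columns are errors; a core-only variant with just the 7
  core features is accepted for externally produced tables).
- Contours: JSON-lines, one grain per line with vertices in μm.
- Grain images: 8-bit PNG plus a sidecar manifest CSV with the pixel size.
- Pipeline/cohort configuration: YAML.
- HPD polygons: GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, FEATURE_COLUMNS
from .errors import SchemaError
from .morphometry import CORE_FEATURE_NAMES
from .shapes import Contour

__all__ = [
    "write_feature_csv", "read_feature_csv",
    "write_contours_jsonl", "read_contours_jsonl",
    "write_image_png", "save_config", "load_config",
    "hpd_to_geojson",
]

_ID_COLUMNS = ("grain_id", "taxon", "view")
#: extra per-grain measurement columns tolerated in feature CSVs
_OPTIONAL_COLUMNS = ("e_protocol", "mfd_minus_e")


def _expected_columns(schema: str) -> List[str]:
    if schema == "all50":
        return [*_ID_COLUMNS, *FEATURE_COLUMNS]
    if schema == "core7":
        return [*_ID_COLUMNS, *CORE_FEATURE_NAMES]
    raise ValueError(f"unknown schema {schema!r}")


def write_feature_csv(table: pd.DataFrame, path) -> None:
    """Write a feature table in the frozen column order (UTF-8 CSV)."""
    schema = "all50" if set(FEATURE_COLUMNS) <= set(table.columns) else "core7"
    cols = _expected_columns(schema)
    cols += [c for c in _OPTIONAL_COLUMNS if c in table.columns]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns: {missing}")
    if table[cols].isna().any().any():
        raise SchemaError("feature table contains missing values")
    table[cols].to_csv(path, index=False)


def read_feature_csv(path, schema: str = "all50") -> pd.DataFrame:
    """Read and validate a feature CSV.

    ``schema="all50"`` requires the full 50-feature table; ``"core7"``
    accepts externally produced tables carrying only the 7 core features.
    Unknown and missing columns are errors naming the offending columns.
    """
    table = pd.read_csv(path)
    expected = _expected_columns(schema)
    allowed = set(expected) | set(_OPTIONAL_COLUMNS)
    if schema == "core7":
        # a full table is a superset of the core schema; tolerate textures
        allowed |= set(FEATURE_COLUMNS)
    unknown = [c for c in table.columns if c not in allowed]
    if unknown:
        raise SchemaError(f"unknown feature columns: {unknown}")
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing}")
    feature_cols = [c for c in table.columns if c not in _ID_COLUMNS]
    if table[feature_cols].isna().any().any():
        raise SchemaError("feature CSV contains missing values")
    return table


def write_contours_jsonl(contours: Iterable[Contour], path) -> None:
    """One grain per line: grain_id, taxon, view, vertices_um, aperture_angles."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in contours:
            rec = {
                "grain_id": c.grain_id,
                "taxon": c.taxon,
                "view": c.view,
                "vertices_um": np.round(c.vertices, 6).tolist(),
                "aperture_angles": (
                    np.round(c.aperture_angles, 9).tolist()
                    if c.aperture_angles is not None else []
                ),
            }
            fh.write(json.dumps(rec) + "\n")


def read_contours_jsonl(path) -> List[Contour]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(Contour(
                vertices=np.asarray(rec["vertices_um"], dtype=float),
                grain_id=rec.get("grain_id"),
                taxon=rec.get("taxon"),
                view=rec.get("view"),
                aperture_angles=(np.asarray(rec["aperture_angles"])
                                 if rec.get("aperture_angles") else None),
            ))
    return out


def write_image_png(image, path) -> None:
    """Save a grain image as 8-bit greyscale PNG."""
    import imageio.v3 as iio

    arr = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).astype(np.uint8))


def save_config(config: CohortConfig, path) -> None:
    """Round-trippable YAML serialization of a cohort configuration."""
    doc = {
        "profiles": {k: int(v) for k, v in config.profiles.items()},
        "view_mix": float(config.view_mix),
        "seed": int(config.seed),
        "pixel_size": float(config.pixel_size),
        "n_vertices": int(config.n_vertices),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return CohortConfig(
        profiles=dict(doc["profiles"]),
        view_mix=float(doc.get("view_mix", 1.0)),
        seed=int(doc.get("seed", 0)),
        pixel_size=float(doc.get("pixel_size", 0.25)),
        n_vertices=int(doc.get("n_vertices", 600)),
    )


def hpd_to_geojson(regions: dict, path=None) -> dict:
    """Serialize {label: HPDRegion} to a GeoJSON FeatureCollection."""
    features = []
    for label, region in regions.items():
        coords = [np.vstack([p, p[:1]]).tolist() for p in region.polygons]
        features.append({
            "type": "Feature",
            "properties": {
                "label": label,
                "mass": region.mass,
                "total_area": region.total_area,
            },
            "geometry": {"type": "MultiPolygon",
                         "coordinates": [[ring] for ring in coords]},
        })
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    return doc
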