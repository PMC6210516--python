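"""Readers and writers for block tables and GeoJSON point layers.

Coordinates are projected planar meters; GeoJSON output is a plain
FeatureCollection of points whose (non-geodetic) CRS is declared in the
top-level properties.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["read_block_table", "write_block_table", "write_geojson_points"]

CSV_COLUMNS = ["block_id", "u", "v", "n_tested", "n_elevated", "rate",
               "building_year", "tax_value", "log_tax", "soil_lead"]


def read_block_table(path) -> pd.DataFrame:
    """Read a block-table CSV (see ``CSV_COLUMNS`` for the full schema)."""
    df = pd.read_csv(path)
    missing = {"u", "v"} - set(df.columns)
    if missing:
        raise ValueError(f"block table lacks coordinate columns {missing}")
    return df


def write_block_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in CSV_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, index=False)


def write_geojson_points(table: pd.DataFrame, path, properties=None,
                         id_column: str = "block_id") -> dict:
    """Write rows as a GeoJSON FeatureCollection of planar points.

    ``properties`` selects the attribute columns (defaults to every column
    except u/v).  Returns the written mapping.
    """
    props = properties or [c for c in table.columns if c not in ("u", "v")]
    features = []
    for _, row in table.iterrows():
        feat = {
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["u"]), float(row["v"])]},
            "properties": {c: _jsonable(row[c]) for c in props},
        }
        if id_column in table.columns:
            feat["id"] = str(row[id_column])
        features.append(feat)
    collection = {
        "type": "FeatureCollection",
        "properties": {"coordinate_system": "local planar meters"},
        "features": features,
    }
    Path(path).write_text(json.dumps(collection))
    return collection


def _jsonable(v):
    if pd.isna(v):
        return None
    if hasattr(v, "item"):
        v = v.item()
    if isinstance(v, float):
        return v
    if isinstance(v, (int, str, bool)):
        return v
    return str(v)
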