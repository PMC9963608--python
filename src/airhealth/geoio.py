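"""Unit-table and station I/O on a single planar CRS.

The unit table is a plain :class:`pandas.DataFrame` with a ``unit_id``
column, a ``city`` group label, a shapely ``geometry`` column of
polygons, and one column per indicator attribute.  It round-trips
through GeoJSON with attributes in feature properties.  Stations travel
as a four-column CSV (``id,x,y,pm25``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape, mapping

#: the ten per-unit indicator attributes of the evaluation system
INDICATOR_COLUMNS = [
    "pop_density",
    "female_density",
    "under14_density",
    "over65_density",
    "residential_neighborhoods",
    "medical_points",
    "forest_share",
    "gdp",
    "tourist_spots",
    "research_edu",
]

CRS_TAG = "local-planar-metres"


def units_to_geojson(units: pd.DataFrame, path: str | Path) -> None:
    """Write a unit table as a GeoJSON FeatureCollection.

    Every non-geometry column becomes a feature property; the CRS tag is
    carried in a top-level ``crs_tag`` member and checked on read.
    """
    features = []
    prop_cols = [c for c in units.columns if c != "geometry"]
    for _, row in units.iterrows():
        props = {}
        for c in prop_cols:
            v = row[c]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            props[c] = v
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "crs_tag": CRS_TAG, "features": features}
    Path(path).write_text(json.dumps(doc))


def units_from_geojson(path: str | Path) -> pd.DataFrame:
    """Read a unit table written by :func:`units_to_geojson`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("crs_tag", CRS_TAG) != CRS_TAG:
        raise ValueError(f"CRS tag mismatch: {doc.get('crs_tag')!r} != {CRS_TAG!r}")
    records = []
    geoms = []
    for feat in doc["features"]:
        records.append(feat["properties"])
        geoms.append(shape(feat["geometry"]))
    units = pd.DataFrame.from_records(records)
    units["geometry"] = geoms
    return units


def stations_to_csv(stations: pd.DataFrame, path: str | Path) -> None:
    stations[["id", "x", "y", "pm25"]].to_csv(path, index=False)


def stations_from_csv(path: str | Path) -> pd.DataFrame:
    stations = pd.read_csv(path)
    required = {"id", "x", "y", "pm25"}
    missing = required - set(stations.columns)
    if missing:
        raise ValueError(f"station CSV missing columns: {sorted(missing)}")
    if stations["id"].duplicated().any():
        raise ValueError("station ids must be unique")
    if (stations["pm25"] < 0).any():
        raise ValueError("pm25 must be non-negative")
    return stations


def validate_units(units: pd.DataFrame, require_attributes: bool = True) -> None:
    """Reject malformed unit tables (missing columns, NaNs, bad geometry).

    Missing attribute values are rejected rather than imputed; callers
    that want a fill policy must apply it explicitly before entry.
    """
    if "unit_id" not in units.columns or "geometry" not in units.columns:
        raise ValueError("unit table needs 'unit_id' and 'geometry' columns")
    if units["unit_id"].duplicated().any():
        raise ValueError("unit ids must be unique")
    if require_attributes:
        missing = [c for c in INDICATOR_COLUMNS if c not in units.columns]
        if missing:
            raise ValueError(f"unit table missing attributes: {missing}")
        block = units[INDICATOR_COLUMNS]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise ValueError(
                f"missing values in attributes {bad}; supply an explicit fill "
                "policy upstream — the pipeline does not impute"
            )
    if not shapely.is_valid(np.asarray(units["geometry"], dtype=object)).all():
        raise ValueError("invalid polygon geometry in unit table")
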