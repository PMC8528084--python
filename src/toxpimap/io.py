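"""Readers and writers: data CSV, pre-scored CSV, GeoJSON, sidecars.

All map layers are emitted as RFC 7946 GeoJSON FeatureCollections —
coordinates in WGS84 lon/lat order, exterior rings counterclockwise,
6 decimal places (~0.1 m) — plus a small JSON styling/metadata sidecar
carrying the layer role, advisory zoom hints and the choropleth legend.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.polygon import orient

from .errors import ParseError, ValidationError
from .layers import Feature, FeatureLayer, LayerRole
from .model import ToxPiModel
from .scoring import DataMatrix, ToxPiResults, compute_overall


@dataclass(frozen=True)
class ColumnMapping:
    """Names of the id / latitude / longitude columns in an input CSV."""

    id: str = "id"
    lat: str = "lat"
    lon: str = "lon"


def read_data_csv(path, mapping: ColumnMapping = ColumnMapping()) -> DataMatrix:
    """Load a component data matrix; row order is preserved.

    Errors carry the offending id or CSV line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={mapping.id: str})
    for col in (mapping.id, mapping.lat, mapping.lon):
        if col not in df.columns:
            raise ParseError(f"{path.name}: required column {col!r} not found")
    ids = df[mapping.id]
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()]))
        raise ValidationError(f"{path.name}: duplicate record id(s): {dupes}")
    for col in (mapping.lat, mapping.lon):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            line = int((df[col].isna() | bad).idxmax()) + 2
            raise ParseError(f"{path.name}: unparseable or missing {col!r} at line {line}")
    value_cols = [c for c in df.columns if c not in (mapping.id, mapping.lat, mapping.lon)]
    values = df[value_cols].copy()
    for col in value_cols:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r} at line {line}"
            )
        values[col] = coerced
    values.index = pd.Index(ids, name=mapping.id)
    return DataMatrix(
        values=values,
        lat=pd.Series(pd.to_numeric(df[mapping.lat]).to_numpy(), index=values.index),
        lon=pd.Series(pd.to_numeric(df[mapping.lon]).to_numpy(), index=values.index),
    )


def read_prescored_csv(path, model: ToxPiModel,
                       mapping: ColumnMapping = ColumnMapping(),
                       overall_col: str = "overall") -> ToxPiResults:
    """Load externally computed ToxPi results (e.g. a GUI export adapted to
    this schema): id, lat, lon, overall, one column per slice score.

    Scores are validated to [0, 1]; unknown extra columns are ignored with
    a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={mapping.id: str})
    needed = [mapping.id, mapping.lat, mapping.lon, overall_col]
    missing_slices = [s for s in model.slice_names if s not in df.columns]
    if missing_slices:
        raise ParseError(
            f"{path.name}: missing slice score column(s) {missing_slices}; "
            f"expected one per model slice: {model.slice_names}"
        )
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path.name}: required column {col!r} not found")
    extras = [c for c in df.columns
              if c not in needed and c not in model.slice_names]
    if extras:
        warnings.warn(f"{path.name}: ignoring unknown column(s) {extras}")
    df = df.set_index(pd.Index(df[mapping.id], name=mapping.id))
    ss = df[model.slice_names].astype(float)
    overall = df[overall_col].astype(float)
    if ((ss < 0) | (ss > 1)).any().any() or ((overall < 0) | (overall > 1)).any():
        raise ValidationError(f"{path.name}: scores must lie in [0, 1]")
    return ToxPiResults(
        model=model,
        slice_scores=ss,
        overall=overall.rename("overall"),
        lat=df[mapping.lat].astype(float),
        lon=df[mapping.lon].astype(float),
    )


# -- GeoJSON -------------------------------------------------------------

def _round_coords(obj, ndigits: int = 6):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, ndigits) for o in obj]
    return round(float(obj), ndigits)


def _to_wgs84_geometry(geom, crs):
    """Reproject a shapely geometry to lon/lat and orient rings CCW."""
    if crs is not None:
        import shapely.ops

        def tx(x, y, z=None):
            lat, lon = crs.unproject(np.asarray(x), np.asarray(y))
            return np.asarray(lon), np.asarray(lat)

        geom = shapely.ops.transform(tx, geom)
    if geom.geom_type == "Polygon":
        geom = orient(geom, sign=1.0)
    elif geom.geom_type == "MultiPolygon":
        from shapely.geometry import MultiPolygon

        geom = MultiPolygon([orient(g, sign=1.0) for g in geom.geoms])
    return geom


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and v != v:
        return None
    return v


def write_geojson(layer: FeatureLayer, path, precision: int = 6,
                  sidecar: bool = True) -> Path:
    """Write a layer as an RFC 7946 FeatureCollection (+ JSON sidecar).

    Projected geometries are reprojected back to WGS84; coordinates are
    serialized at ``precision`` decimal places.
    """
    path = Path(path)
    features = []
    for f in layer.features:
        geom = _to_wgs84_geometry(f.geometry, layer.crs)
        gj = shapely_mapping(geom)
        gj = {"type": gj["type"],
              "coordinates": _round_coords(gj["coordinates"], precision)}
        features.append(
            {
                "type": "Feature",
                "geometry": gj,
                "properties": {k: _jsonable(v) for k, v in f.properties.items()},
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(fc) + "\n")
    if sidecar:
        write_sidecar(layer, path.with_suffix(".style.json"))
    return path


def write_sidecar(layer: FeatureLayer, path) -> Path:
    """Advisory rendering metadata: role, zoom hints, legend."""
    meta = {
        "name": layer.name,
        "role": layer.role.value,
        "scale_hint": (
            None if layer.scale_hint is None
            else {"min_zoom": layer.scale_hint[0], "max_zoom": layer.scale_hint[1]}
        ),
        "legend": (
            None if layer.legend is None
            else [
                {"lower": c.lower, "upper": c.upper, "color": c.color, "label": c.label}
                for c in layer.legend
            ]
        ),
        "feature_count": len(layer.features),
    }
    path = Path(path)
    path.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_geojson(path) -> list[Feature]:
    """Read a FeatureCollection into shapely geometries + property dicts."""
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: not a GeoJSON FeatureCollection")
    return [
        Feature(geometry=shapely_shape(f["geometry"]),
                properties=dict(f.get("properties") or {}))
        for f in data["features"]
    ]


def read_boundaries(path, id_property: str = "record_id") -> dict:
    """Boundary polygons keyed by the ``id_property`` feature property."""
    out = {}
    for f in read_geojson(path):
        key = f.properties.get(id_property)
        if key is None:
            raise ParseError(
                f"{path}: boundary feature lacks the {id_property!r} property"
            )
        out[str(key)] = f.geometry
    return out


def write_boundaries(boundaries: dict, path,
                     id_property: str = "record_id") -> Path:
    """Write WGS84 boundary polygons as a FeatureCollection."""
    layer = FeatureLayer(
        role=LayerRole.LOCAL_CHOROPLETH,
        features=[
            Feature(geometry=g, properties={id_property: str(k)})
            for k, g in boundaries.items()
        ],
        crs=None,
        name="boundaries",
    )
    return write_geojson(layer, path, sidecar=False)
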