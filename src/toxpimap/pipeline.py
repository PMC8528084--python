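"""One-shot pipeline: raw component CSV in, a full set of map layers out.

Mirrors the "two required parameters" workflow: given only an input CSV and
an output directory, the pipeline discovers conventional sibling files
(``model.json``, ``boundaries.geojson``, ``groups.csv`` next to the input),
scores every record, and emits six GeoJSON layers — local glyphs, a
shrunken dense-area copy, group-median glyphs, local and group choropleths,
and maximum-radius rings — plus scores, hotspot results, and styling
sidecars.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from shapely.ops import unary_union

from .geometry import GlyphSpec
from .hotspot import BIN_COLORS, HotspotAnalysis
from .io import ColumnMapping, read_boundaries, read_data_csv, write_geojson
from .layers import (
    Feature,
    FeatureLayer,
    LayerRole,
    attach_scale_hints,
    build_choropleth,
    build_dense_layer,
    build_group_glyph_layer,
    build_local_glyph_layer,
    build_rings_layer,
)
from .model import ToxPiModel
from .scoring import aggregate_group_medians, score
from .simulate import pvi_like_model

logger = logging.getLogger(__name__)

# advisory zoom ranges: group layers when zoomed out, local when zoomed in,
# dense (small glyph) layer at the closest zooms
ZOOM_HINTS = {
    LayerRole.GROUP_GLYPH: (0, 7),
    LayerRole.GROUP_CHOROPLETH: (0, 7),
    LayerRole.LOCAL_GLYPH: (8, 22),
    LayerRole.LOCAL_GLYPH_DENSE: (10, 22),
    LayerRole.LOCAL_CHOROPLETH: (8, 22),
    LayerRole.RINGS: (8, 22),
}


def _discover(input_csv: Path, explicit, name: str):
    if explicit is not None:
        return Path(explicit)
    candidate = input_csv.parent / name
    return candidate if candidate.exists() else None


def run_all(
    input_csv,
    output_dir,
    model_path=None,
    boundaries_path=None,
    groups_path=None,
    mapping: ColumnMapping = ColumnMapping(),
    radius_max: float = 10_000.0,
    shrink: float = 0.5,
    group_radius_factor: float = 3.0,
    crs=5070,
    band_miles: float = 50.0,
    fdr: bool = True,
    k_classes: int = 5,
) -> dict[str, Path]:
    """Score, draw, aggregate, classify and hotspot-analyze in one call.

    Returns a name -> path mapping of everything written.
    """
    input_csv = Path(input_csv)
    if not input_csv.exists():
        raise FileNotFoundError(f"input file not found: {input_csv}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    model_path = _discover(input_csv, model_path, "model.json")
    model = ToxPiModel.from_json(model_path) if model_path else pvi_like_model()
    matrix = read_data_csv(input_csv, mapping)
    results = score(matrix, model)

    paths: dict[str, Path] = {}
    scores_csv = out / "scores.csv"
    results.to_frame().to_csv(scores_csv, index_label=mapping.id)
    paths["scores"] = scores_csv

    groups_path = _discover(input_csv, groups_path, "groups.csv")
    if groups_path:
        gdf = pd.read_csv(groups_path, dtype=str)
        grouping = pd.Series(gdf["group"].values, index=gdf[mapping.id].values)
    else:
        logger.info("no groups.csv found; treating the cohort as one group")
        grouping = pd.Series("all", index=results.slice_scores.index)
    group_results = aggregate_group_medians(results, grouping)

    spec = GlyphSpec(radius_max=radius_max)
    group_spec = GlyphSpec(radius_max=radius_max * group_radius_factor)

    layers = {
        "local_glyphs": build_local_glyph_layer(results, spec, crs=crs),
        "local_glyphs_dense": build_dense_layer(results, spec, shrink=shrink, crs=crs),
        "group_glyphs": build_group_glyph_layer(group_results, group_spec, crs=crs),
        "rings": build_rings_layer(results, spec, crs=crs),
    }

    boundaries_path = _discover(input_csv, boundaries_path, "boundaries.geojson")
    boundaries = None
    if boundaries_path:
        boundaries = read_boundaries(boundaries_path)
        layers["local_choropleth"] = build_choropleth(
            results, boundaries, k=k_classes,
            role=LayerRole.LOCAL_CHOROPLETH, name="local_choropleth",
        )
        group_bounds = {}
        for g in group_results.record_ids:
            members = [r for r in results.record_ids
                       if grouping.get(r) == g and r in boundaries]
            if members:
                group_bounds[g] = unary_union([boundaries[r] for r in members])
        k_group = min(k_classes, max(2, len(group_bounds)))
        layers["group_choropleth"] = build_choropleth(
            group_results, group_bounds, k=k_group,
            role=LayerRole.GROUP_CHOROPLETH, name="group_choropleth",
        )
    else:
        logger.warning(
            "no boundary polygons found next to %s; choropleth layers skipped",
            input_csv.name,
        )

    for name, layer in layers.items():
        attach_scale_hints(layer, *ZOOM_HINTS[layer.role])
        paths[name] = write_geojson(layer, out / f"{name}.geojson")

    # hotspot analysis of the overall score
    hot = HotspotAnalysis(results, field="overall", band_miles=band_miles).fit(fdr=fdr)
    hotspot_csv = out / "hotspot.csv"
    hot.table.to_csv(hotspot_csv, index_label=mapping.id)
    paths["hotspot_csv"] = hotspot_csv
    paths["hotspot_layer"] = write_geojson(
        hotspot_layer(hot.table, results, boundaries), out / "hotspot.geojson"
    )
    return paths


def hotspot_layer(table: pd.DataFrame, results, boundaries=None) -> FeatureLayer:
    """Bin-colored hotspot layer: boundary choropleth when polygons are
    available, points otherwise (hot red / cold blue)."""
    from shapely.geometry import Point

    feats = []
    for rid, row in table.iterrows():
        b = int(row["bin"])
        props = {
            "record_id": str(rid),
            "value": float(row["value"]),
            "gi_z": float(row["gi_z"]),
            "p": float(row["p"]),
            "p_adj": float(row["p_adj"]),
            "bin": b,
            "fill": BIN_COLORS[b],
        }
        if boundaries is not None and str(rid) in boundaries:
            geom = boundaries[str(rid)]
        else:
            geom = Point(float(results.lon.loc[rid]), float(results.lat.loc[rid]))
        feats.append(Feature(geometry=geom, properties=props))
    return FeatureLayer(role=LayerRole.HOTSPOT, features=feats, crs=None,
                        name="hotspot")
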