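"""Multi-scale map layer assembly.

The map product mirrors a zoom-aware county map: a local glyph layer, a
shrunken copy for dense areas, a group-level (e.g. state) median glyph
layer, quantile choropleths of the overall score at both scales, and
optional maximum-radius rings. Zoom switching itself is a renderer concern;
layers only carry advisory ``scale_hint`` metadata that the GeoJSON sidecar
preserves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from shapely.geometry.base import BaseGeometry

from .crs import AlbersEqualArea, get_crs
from .errors import ConfigurationError, ValidationError
from .geometry import GlyphSpec, build_glyph, build_ring
from .scoring import ToxPiResults


class LayerRole(str, Enum):
    LOCAL_GLYPH = "local_glyph"
    LOCAL_GLYPH_DENSE = "local_glyph_dense"
    GROUP_GLYPH = "group_glyph"
    LOCAL_CHOROPLETH = "local_choropleth"
    GROUP_CHOROPLETH = "group_choropleth"
    RINGS = "rings"
    HOTSPOT = "hotspot"


@dataclass(frozen=True)
class Feature:
    geometry: BaseGeometry
    properties: dict


@dataclass(frozen=True)
class ChoroplethClass:
    lower: float
    upper: float
    color: str
    label: str


@dataclass
class FeatureLayer:
    """A typed feature collection plus advisory rendering metadata.

    ``crs`` is the projected system the geometries live in, or None when
    they are already geographic WGS84 lon/lat (choropleth boundaries).
    """

    role: LayerRole
    features: list[Feature]
    crs: AlbersEqualArea | None = None
    scale_hint: tuple[int, int] | None = None
    legend: list[ChoroplethClass] | None = None
    name: str = ""

    def __len__(self) -> int:
        return len(self.features)


# 3..9-class sequential ramp anchors (light -> dark red), interpolated for
# other k; chosen to read like a standard YlOrRd choropleth.
_RAMP_ANCHORS = ["#ffffb2", "#fecc5c", "#fd8d3c", "#f03b20", "#bd0026"]


def _interp_ramp(k: int) -> list[str]:
    anchors = np.array(
        [[int(c[i:i + 2], 16) for i in (1, 3, 5)] for c in _RAMP_ANCHORS], float
    )
    pos = np.linspace(0, 1, len(anchors))
    out = []
    for t in np.linspace(0, 1, k):
        rgb = [int(round(np.interp(t, pos, anchors[:, ch]))) for ch in range(3)]
        out.append("#{:02x}{:02x}{:02x}".format(*rgb))
    return out


def quantile_classes(scores, k: int = 5) -> list[ChoroplethClass]:
    """Contiguous quantile class breaks covering the observed score range.

    Duplicate quantile edges (heavily tied data) collapse the class count
    with a warning; all-equal scores yield a single class.
    """
    if k < 2:
        raise ConfigurationError("choropleth class count k must be >= 2")
    x = np.asarray(scores, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, k + 1)))
    if len(edges) < 2:
        warnings.warn("all scores identical; choropleth collapses to one class")
        edges = np.array([edges[0], edges[0]])
    elif len(edges) < k + 1:
        warnings.warn(
            f"tied scores collapse choropleth from {k} to {len(edges) - 1} classes"
        )
    colors = _interp_ramp(len(edges) - 1)
    classes = []
    for i in range(len(edges) - 1):
        classes.append(
            ChoroplethClass(
                lower=float(edges[i]),
                upper=float(edges[i + 1]),
                color=colors[i],
                label=f"{edges[i]:.3f}–{edges[i + 1]:.3f}",
            )
        )
    return classes


def classify(value: float, classes: list[ChoroplethClass]) -> int:
    """Index of the class containing ``value`` (upper edges inclusive)."""
    for i, c in enumerate(classes):
        if value <= c.upper or i == len(classes) - 1:
            return i
    return len(classes) - 1


def _glyph_features(results: ToxPiResults, crs: AlbersEqualArea,
                    spec: GlyphSpec, extra: dict | None = None) -> list[Feature]:
    ids = results.record_ids
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate record ids in results")
    feats = []
    for rid in ids:
        x, y = crs.project(float(results.lat.loc[rid]), float(results.lon.loc[rid]))
        for wedge in build_glyph(results, rid, (x, y), spec):
            props = dict(wedge.attributes)
            if extra:
                props.update(extra.get(rid, {}))
            feats.append(Feature(geometry=wedge.polygon, properties=props))
    return feats


def build_local_glyph_layer(results: ToxPiResults, spec: GlyphSpec,
                            crs=5070) -> FeatureLayer:
    """One wedge feature per record per slice, at each record's location."""
    crs = get_crs(crs)
    return FeatureLayer(
        role=LayerRole.LOCAL_GLYPH,
        features=_glyph_features(results, crs, spec),
        crs=crs,
        name="local_glyphs",
    )


def build_dense_layer(results: ToxPiResults, spec: GlyphSpec,
                      shrink: float = 0.5, crs=5070) -> FeatureLayer:
    """The local layer redrawn at ``radius_max * shrink`` for dense areas."""
    if not 0 < shrink < 1:
        raise ConfigurationError("shrink must lie strictly between 0 and 1")
    crs = get_crs(crs)
    small = replace(spec, radius_max=spec.radius_max * shrink)
    return FeatureLayer(
        role=LayerRole.LOCAL_GLYPH_DENSE,
        features=_glyph_features(results, crs, small),
        crs=crs,
        name="local_glyphs_dense",
    )


def build_group_glyph_layer(group_results: ToxPiResults, spec: GlyphSpec,
                            crs=5070, centroids=None) -> FeatureLayer:
    """One glyph per group at its centroid (default: mean member location).

    ``group_results`` comes from ``aggregate_group_medians``; ``centroids``
    may override positions with a mapping label -> (lat, lon).
    """
    crs = get_crs(crs)
    res = group_results
    if centroids is not None:
        missing = [g for g in res.record_ids if g not in centroids]
        if missing:
            raise ValidationError(f"no centroid provided for group(s): {missing}")
        res = ToxPiResults(
            model=res.model,
            slice_scores=res.slice_scores,
            overall=res.overall,
            lat=res.lat.__class__({g: centroids[g][0] for g in res.record_ids}),
            lon=res.lon.__class__({g: centroids[g][1] for g in res.record_ids}),
            raw=res.raw,
        )
    extra = {g: {"group": str(g)} for g in res.record_ids}
    return FeatureLayer(
        role=LayerRole.GROUP_GLYPH,
        features=_glyph_features(res, crs, spec, extra=extra),
        crs=crs,
        name="group_glyphs",
    )


def build_rings_layer(results: ToxPiResults, spec: GlyphSpec,
                      crs=5070) -> FeatureLayer:
    """One maximum-radius circle per record."""
    crs = get_crs(crs)
    feats = []
    for rid in results.record_ids:
        x, y = crs.project(float(results.lat.loc[rid]), float(results.lon.loc[rid]))
        ring = build_ring((x, y), spec.radius_max, spec.arc_step)
        feats.append(Feature(geometry=ring, properties={"record_id": str(rid)}))
    return FeatureLayer(role=LayerRole.RINGS, features=feats, crs=crs, name="rings")


def build_choropleth(results: ToxPiResults, boundaries: dict,
                     k: int = 5, role: LayerRole = LayerRole.LOCAL_CHOROPLETH,
                     name: str = "choropleth") -> FeatureLayer:
    """Boundary polygons classed by overall score (quantile breaks).

    ``boundaries`` maps record id -> WGS84 shapely polygon. Ids without a
    boundary are skipped with a warning.
    """
    ids = [r for r in results.record_ids if r in boundaries]
    missing = [r for r in results.record_ids if r not in boundaries]
    if missing:
        warnings.warn(f"no boundary polygon for {len(missing)} record(s); skipped")
    scores = results.overall.loc[ids].to_numpy(dtype=float)
    classes = quantile_classes(scores, k) if len(ids) else []
    feats = []
    for rid, sc in zip(ids, scores):
        ci = classify(float(sc), classes)
        feats.append(
            Feature(
                geometry=boundaries[rid],
                properties={
                    "record_id": str(rid),
                    "overall_score": float(sc),
                    "class_index": ci,
                    "class_label": classes[ci].label,
                    "fill": classes[ci].color,
                },
            )
        )
    return FeatureLayer(role=role, features=feats, crs=None, legend=classes, name=name)


def attach_scale_hints(layer: FeatureLayer, min_zoom: int,
                       max_zoom: int) -> FeatureLayer:
    """Set advisory zoom visibility metadata; geometry is untouched."""
    if min_zoom > max_zoom:
        raise ConfigurationError("min_zoom must be <= max_zoom")
    layer.scale_hint = (int(min_zoom), int(max_zoom))
    return layer
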