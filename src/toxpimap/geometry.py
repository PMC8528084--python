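"""Radar-glyph ("ToxPi figure") wedge geometry in projected meters.

Each record's glyph is a pie of wedge polygons, one per slice: the angular
width of slice *i* is proportional to its weight (360 * w_i / sum(w)), and
its radial extent is the slice score times the glyph's maximum radius. The
first slice starts at north (bearing 0) and slices proceed clockwise,
matching the ToxPi GUI's visual convention. Arcs are discretized every
``arc_step`` degrees; at the 5-degree default the area of a full disc is
within 0.13% of pi*r^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import ConfigurationError, ValidationError
from .model import ToxPiModel
from .scoring import ToxPiResults


@dataclass(frozen=True)
class GlyphSpec:
    """Drawing parameters shared by every glyph in a layer.

    radius_max : maximum wedge radius in meters (a slice score of 1 reaches it)
    arc_step : arc discretization in degrees per vertex
    min_radius_fraction : radial floor so zero-score slices stay clickable
    start_bearing : bearing (degrees clockwise from north) of the first slice
    """

    radius_max: float = 10_000.0
    arc_step: float = 5.0
    min_radius_fraction: float = 0.01
    start_bearing: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_max <= 0:
            raise ConfigurationError("radius_max must be > 0")
        if not 0 < self.arc_step <= 90:
            raise ConfigurationError("arc_step must be in (0, 90] degrees")
        if not 0 <= self.min_radius_fraction <= 1:
            raise ConfigurationError("min_radius_fraction must be in [0, 1]")


@dataclass(frozen=True)
class WedgePolygon:
    """One slice of one glyph: a closed ring plus popup attributes."""

    polygon: Polygon
    attributes: dict


def slice_angles(weights, start_bearing: float = 0.0) -> list[tuple[float, float]]:
    """Partition the circle into weight-proportional clockwise sectors.

    Returns (start, end) bearing pairs in degrees; the last sector's end is
    pinned to ``start_bearing + 360`` exactly so the disc closes despite
    floating-point accumulation.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w <= 0):
        raise ConfigurationError("all slice weights must be > 0")
    widths = 360.0 * w / w.sum()
    edges = start_bearing + np.concatenate([[0.0], np.cumsum(widths)])
    edges[-1] = start_bearing + 360.0  # last slice absorbs rounding
    return [(float(edges[i]), float(edges[i + 1])) for i in range(len(w))]


def _arc_points(cx: float, cy: float, start: float, end: float, radius: float,
                arc_step: float) -> np.ndarray:
    n_seg = max(1, math.ceil((end - start) / arc_step - 1e-12))
    bearings = np.radians(np.linspace(start, end, n_seg + 1))
    # bearing convention: clockwise from north => x ~ sin, y ~ cos
    return np.column_stack([cx + radius * np.sin(bearings),
                            cy + radius * np.cos(bearings)])


def build_wedge(center, start: float, end: float, radius: float,
                arc_step: float = 5.0) -> Polygon:
    """A circular sector from bearing ``start`` clockwise to ``end``.

    The ring runs center -> arc -> center. A full 360-degree sector is
    emitted as a plain circle (no center vertex) to avoid a degenerate slit.
    """
    if radius <= 0:
        raise ConfigurationError("wedge radius must be > 0")
    if end <= start:
        raise ConfigurationError("end bearing must exceed start (clockwise sweep)")
    if end - start > 360.0 + 1e-9:
        raise ConfigurationError("sector sweep cannot exceed 360 degrees")
    cx, cy = float(center[0]), float(center[1])
    arc = _arc_points(cx, cy, start, end, radius, arc_step)
    if abs((end - start) - 360.0) < 1e-9:
        # drop the duplicated end vertex; shapely closes the ring exactly
        return Polygon(arc[:-1])
    coords = np.vstack([[cx, cy], arc, [cx, cy]])
    return Polygon(coords)


def build_ring(center, radius_max: float, arc_step: float = 5.0) -> Polygon:
    """Closed circle approximation marking a glyph's maximum radius."""
    if radius_max <= 0:
        raise ConfigurationError("radius_max must be > 0")
    return build_wedge(center, 0.0, 360.0, radius_max, arc_step)


def build_glyph(
    results: ToxPiResults,
    record_id: str,
    center,
    spec: GlyphSpec,
    slice_subset: list[str] | None = None,
) -> list[WedgePolygon]:
    """All wedge polygons of one record's glyph at a projected center point.

    When ``slice_subset`` is given, only those slices are drawn and the
    angular partition is recomputed from the subset's weights (the sectors
    still tile the full circle). Wedge radius is
    ``max(score, min_radius_fraction) * radius_max``.
    """
    model = results.model
    if slice_subset is not None:
        model = model.subset(slice_subset)
    if record_id not in results.slice_scores.index:
        raise ValidationError(f"unknown record id {record_id!r}")
    row = results.slice_scores.loc[record_id]
    overall = float(results.overall.loc[record_id])
    angles = slice_angles(model.weights, spec.start_bearing)
    total_w = sum(model.weights)
    wedges = []
    for s, (start, end) in zip(model.slices, angles):
        sc = float(row[s.name])
        radius = max(sc, spec.min_radius_fraction) * spec.radius_max
        attrs = {
            "record_id": str(record_id),
            "slice": s.name,
            "domain": s.domain,
            "slice_score": sc,
            "weight_fraction": s.weight / total_w,
            "color": s.color,
            "overall_score": overall,
        }
        if results.raw is not None:
            for c in s.components:
                v = results.raw.loc[record_id, c.name]
                attrs[f"raw::{c.name}"] = None if v != v else float(v)
        poly = build_wedge(center, start, end, radius, spec.arc_step)
        wedges.append(WedgePolygon(polygon=poly, attributes=attrs))
    return wedges
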