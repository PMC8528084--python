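"""Synthetic county-like fixtures for end-to-end testing.

Real county-level vulnerability data (locations, boundary shapes, component
measurements) cannot be bundled, so this module generates a regular
point lattice with square "county" boundary cells, vertical "state" bands
as group labels, a 4-domain / 14-slice pandemic-vulnerability-style ToxPi
model, and component matrices of i.i.d. Uniform(0, 1) baseline noise with
optional planted high-score spatial clusters.

What this emulates: cohort-relative scoring, glyph/choropleth layer
assembly, and hotspot recovery of spatially compact elevated regions. What
it does not: real counties' irregular shapes and areas, spatially
autocorrelated or heavy-tailed component distributions, and missingness
patterns of survey data — so passing tests demonstrate correctness of the
machinery, not performance claims about real surveillance data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ConfigurationError
from .hotspot import haversine_m
from .model import ComponentDefinition, Direction, SliceDefinition, ToxPiModel
from .scoring import DataMatrix

KM_PER_DEG_LAT = 111.1949  # pi * R_mean / 180 with R = 6371.0088 km


def pvi_like_model() -> ToxPiModel:
    """A 4-domain / 14-slice vulnerability model in the PVI-with-vaccine shape.

    Domains: infection rate, population concentration, intervention
    measures, and health & environment. Slice weights are documented
    placeholders (the published per-slice weights are only available as a
    figure); intervention slices are protective, so their components are
    lower-is-worse.
    """
    H, L = Direction.HIGHER_IS_WORSE, Direction.LOWER_IS_WORSE

    def comp(name, direction=H, weight=1.0):
        return ComponentDefinition(name=name, direction=direction, weight=weight)

    spec = [
        # (slice, domain, weight, color, components)
        ("Transmissible Cases", "Infection Rate", 3.0, "#99000d",
         [comp("cases_per_capita"), comp("test_positivity")]),
        ("Disease Spread", "Infection Rate", 3.0, "#ef3b2c",
         [comp("spread_rate")]),
        ("Population Mobility", "Population Concentration", 1.0, "#ec7014",
         [comp("mobility_index")]),
        ("Residential Density", "Population Concentration", 1.0, "#fe9929",
         [comp("residential_density")]),
        ("Daytime Density", "Population Concentration", 1.0, "#fec44f",
         [comp("daytime_density")]),
        ("Social Distancing", "Intervention Measures", 2.0, "#005a32",
         [comp("distancing_score", L)]),
        ("Testing", "Intervention Measures", 2.0, "#41ab5d",
         [comp("tests_per_capita", L)]),
        ("Vaccination", "Intervention Measures", 2.0, "#a1d99b",
         [comp("pct_fully_vaccinated", L), comp("pct_one_dose", L)]),
        ("Population Demographics", "Health & Environment", 1.0, "#084594",
         [comp("pct_minority"), comp("pct_poverty")]),
        ("Air Pollution", "Health & Environment", 1.0, "#2171b5",
         [comp("pm25")]),
        ("Age Distribution", "Health & Environment", 1.0, "#4292c6",
         [comp("pct_over_65")]),
        ("Comorbidities", "Health & Environment", 1.0, "#6baed6",
         [comp("comorbidity_index")]),
        ("Health Disparities", "Health & Environment", 1.0, "#9ecae1",
         [comp("uninsured_rate"), comp("disparity_index")]),
        ("Hospital Beds", "Health & Environment", 1.0, "#c6dbef",
         [comp("beds_per_capita", L)]),
    ]
    slices = tuple(
        SliceDefinition(name=n, domain=d, weight=w, color=c, components=tuple(cs))
        for n, d, w, c, cs in spec
    )
    return ToxPiModel(name="pvi-like-synthetic", slices=slices)


@dataclass(frozen=True)
class SimSpec:
    """Lattice and noise parameters for the synthetic cohort.

    A 12 x 12 lattice at 30 km spacing spans roughly a midwestern state;
    ``cluster_centers`` are (lat, lon) pairs whose surrounding records (great
    circle, ``cluster_radius_km``) get ``effect`` added to every
    higher-is-worse component before scaling.
    """

    n_cols: int = 12
    n_rows: int = 12
    origin_lat: float = 36.0
    origin_lon: float = -98.0
    spacing_km: float = 30.0
    cluster_centers: tuple[tuple[float, float], ...] = ()
    cluster_radius_km: float = 60.0  # two lattice cells at default spacing
    effect: float = 0.0
    n_groups: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("lattice must have at least one row and column")
        if self.spacing_km <= 0:
            raise ConfigurationError("lattice spacing must be > 0")
        if self.effect < 0:
            raise ConfigurationError("cluster effect size must be >= 0")

    def center_latlon(self) -> tuple[float, float]:
        """Lattice midpoint, convenient as a default cluster center."""
        dlat = self.spacing_km / KM_PER_DEG_LAT
        dlon = dlat / np.cos(np.radians(self.origin_lat))
        return (
            self.origin_lat + dlat * (self.n_rows - 1) / 2.0,
            self.origin_lon + dlon * (self.n_cols - 1) / 2.0,
        )


def _lattice_coords(spec: SimSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    dlat = spec.spacing_km / KM_PER_DEG_LAT
    dlon = dlat / np.cos(np.radians(spec.origin_lat))
    cols, rows = np.meshgrid(np.arange(spec.n_cols), np.arange(spec.n_rows))
    cols, rows = cols.ravel(), rows.ravel()
    return (
        spec.origin_lat + rows * dlat,
        spec.origin_lon + cols * dlon,
        cols,
        rows,
    )


def generate_lattice(
    spec: SimSpec, model: ToxPiModel | None = None
) -> tuple[DataMatrix, dict[str, Polygon], pd.Series]:
    """Generate the synthetic cohort.

    Returns the component DataMatrix (with any clusters planted), square
    WGS84 boundary polygons centered on each point, and a record -> group
    ("state" band) label Series. Groups split the columns into
    ``n_groups`` contiguous vertical bands, the first ``n_cols % n_groups``
    bands one column wider (numpy ``array_split`` semantics). Fully
    deterministic under ``spec.seed``.
    """
    model = model or pvi_like_model()
    lat, lon, cols, rows = _lattice_coords(spec)
    n = lat.size
    ids = [f"C{r:02d}{c:02d}" for r, c in zip(rows, cols)]
    rng = np.random.default_rng(spec.seed)
    comp_names = model.component_names
    values = pd.DataFrame(
        rng.uniform(0.0, 1.0, size=(n, len(comp_names))),
        index=pd.Index(ids, name="id"),
        columns=comp_names,
    )
    matrix = DataMatrix(values=values, lat=pd.Series(lat, index=values.index),
                        lon=pd.Series(lon, index=values.index))
    if spec.cluster_centers and spec.effect > 0:
        matrix = plant_cluster(matrix, spec, model)

    dlat = spec.spacing_km / KM_PER_DEG_LAT
    dlon = dlat / np.cos(np.radians(spec.origin_lat))
    boundaries = {}
    for rid, la, lo in zip(ids, lat, lon):
        boundaries[rid] = Polygon(
            [
                (lo - dlon / 2, la - dlat / 2),
                (lo + dlon / 2, la - dlat / 2),
                (lo + dlon / 2, la + dlat / 2),
                (lo - dlon / 2, la + dlat / 2),
            ]
        )

    band_of_col = np.concatenate(
        [np.full(len(chunk), b) for b, chunk in
         enumerate(np.array_split(np.arange(spec.n_cols), spec.n_groups))]
    )
    groups = pd.Series(
        [f"state_{band_of_col[c]}" for c in cols], index=values.index, name="group"
    )
    return matrix, boundaries, groups


def plant_cluster(matrix: DataMatrix, spec: SimSpec,
                  model: ToxPiModel | None = None) -> DataMatrix:
    """Add ``spec.effect`` to every higher-is-worse component of records
    within ``cluster_radius_km`` (great circle) of any cluster center."""
    model = model or pvi_like_model()
    if spec.effect == 0 or not spec.cluster_centers:
        return matrix
    values = matrix.values.copy()
    lat = matrix.lat.to_numpy()
    lon = matrix.lon.to_numpy()
    member = np.zeros(len(values), dtype=bool)
    for clat, clon in spec.cluster_centers:
        d = haversine_m(lat, lon, clat, clon)
        member |= d <= spec.cluster_radius_km * 1000.0
    worse = [
        c.name for s in model.slices for c in s.components
        if c.direction is Direction.HIGHER_IS_WORSE and c.name in values.columns
    ]
    values.loc[member, worse] += spec.effect
    return DataMatrix(values=values, lat=matrix.lat, lon=matrix.lon)


def cluster_members(matrix: DataMatrix, spec: SimSpec) -> np.ndarray:
    """Boolean mask of records inside any planted cluster (haversine)."""
    lat = matrix.lat.to_numpy()
    lon = matrix.lon.to_numpy()
    member = np.zeros(len(matrix), dtype=bool)
    for clat, clon in spec.cluster_centers:
        member |= haversine_m(lat, lon, clat, clon) <= spec.cluster_radius_km * 1000.0
    return member
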