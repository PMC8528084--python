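# Methods

## Scoring chain

A ToxPi model is an ordered list of slices, each with a positive weight
`w_i`, a domain (color family), and one or more components with a scaling
direction and a positive within-slice weight. Scoring proceeds in three
steps.

1. **Cohort-relative scaling.** Each component column is linearly min-max
   scaled to [0, 1] over its non-missing entries in the input matrix;
   lower-is-worse (protective) components are inverted (`1 − scaled`).
   Scores are therefore *comparative within the analyzed cohort*, not
   absolute: adding or removing records changes every scaled value.
2. **Slice scores.** `s_i` is the weighted mean of the slice's scaled
   components. The within-slice aggregation rule is this package's own
   choice (a weighted mean with equal default weights); it is the simplest
   rule that keeps `s_i` in [0, 1] and is monotone in each component.
3. **Overall score.** `overall = Σ w_i s_i / Σ w_i`, invariant under
   uniform rescaling of the weights.

Degenerate-input rules, chosen so every record always yields a drawable
glyph: a constant column scales to 0 for all records (not NaN), and
missing values impute to 0 *after* scaling — the most conservative
contribution a component can make. Both events are logged.

**Group aggregation** takes per-slice medians within each group and
*recomputes* the group overall from those median slice scores rather than
taking the median of member overalls. The two differ in general; the
recomputation was chosen so the aggregate glyph's wedge lengths and its
reported overall score remain mutually consistent. Group positions default
to the mean of member locations; a centroid table can override.

## Glyph geometry

Wedges are drawn in a projected CRS in meters. Slice *i* spans a clockwise
sector of width `360 w_i / Σw` starting at north (bearing 0°) with the
first model slice — the radar-chart convention users of the upstream Java
GUI expect; the last sector's end is pinned to exactly 360° so the disc
closes despite floating-point accumulation. Wedge radius is
`max(s_i, min_radius_fraction) · radius_max`; the 0.01 default floor keeps
zero-score slices clickable in interactive maps (set 0 to disable). Arcs
are discretized every `arc_step` degrees (default 5°: a full disc's area
is `(n/2) r² sin(2π/n)` with n = 72, 0.127% below `πr²`, while keeping
files small). The wedge ring runs center → arc → center; a full-circle
sector (single-slice model) is emitted as a plain circle to avoid a
degenerate self-touching slit.

Projection uses the Albers equal-area conic on the GRS80 ellipsoid,
implemented from Snyder's closed-form conic equations with a Newton
iteration for the inverse latitude; the forward transform reproduces
Snyder's published numerical example to sub-millimeter, and round trips
are exact to < 1e-12 degrees. EPSG:5070 (CONUS Albers) is the default so
glyphs at different latitudes have comparable drawn sizes; custom standard
parallels are supported. Equal-area was preferred over conformal because
glyph *size* carries meaning here, shape distortion at the ~10 km glyph
scale being negligible.

## Layers and choropleths

Local and dense layers are identical except for the radius scale factor
(`shrink ∈ (0,1)`, default 0.5); feature order and attribute tables match
one-to-one, so renderers can swap them by zoom level. Zoom switching
itself is a display property of the rendering platform, so layers carry
only advisory `(min_zoom, max_zoom)` hints in a JSON sidecar.

Choropleth classes are quantile breaks (default k = 5) of the observed
overall scores — chosen over equal-interval because vulnerability scores
are typically concentrated mid-range and quantiles keep all classes
populated. Ties collapse duplicate edges (with a warning) rather than
emitting empty classes. Colors interpolate a standard light-to-dark red
sequential ramp; hotspot layers use a fixed seven-color blue-to-red
diverging palette keyed to Gi_Bin.

All GeoJSON output is RFC 7946: WGS84 lon/lat order, counterclockwise
exterior rings, coordinates at 6 decimal places (~0.1 m — below the
arc-discretization error, so precision loss is immaterial).

## Hotspot analysis

Neighborhoods are binary distance bands on great-circle (haversine,
R = 6 371 008.8 m) distances between record coordinates, self included,
band inclusive. Great-circle rather than projected distance keeps the
neighbor graph independent of the drawing CRS; miles convert at exactly
1609.344 m. The Gi* denominator uses the binary-weight simplification
`Σw = Σw² = W_i`. Two degenerate cases return z = 0 with a logged
warning instead of NaN or an error: zero global variance, and a
neighborhood containing all n points (vanishing variance bracket).

p-values are two-sided normal. Binning operates on p rather than raw |z|
cutoffs so that the optional Benjamini-Hochberg FDR adjustment (on by
default, mirroring optimized hotspot tooling; `--no-fdr` disables)
integrates cleanly; with FDR off the bins coincide exactly with the
classic 1.645 / 1.960 / 2.576 thresholds. Whether published county
dashboards bin on adjusted or raw significance is generally unstated, so
both modes are first-class. Band selection is deliberately manual: the
band is a required, documented parameter (50 miles being the convention
for US county analyses), and no automatic band heuristic is provided.

## Synthetic cohort

The simulator emulates county-level vulnerability data at desk scale: an
`n_cols × n_rows` point lattice (default 12 × 12 at 30 km spacing, about
one midwestern state) with square boundary cells, vertical "state" bands
as group labels (columns split by `array_split` semantics: the first
`n_cols mod k` bands get one extra column), i.i.d. Uniform(0, 1) baseline
components, and optional clusters that add an effect δ to every
higher-is-worse component of records within a great-circle radius
(default two cells) of a center — *before* scaling, so cluster planting
exercises the entire scoring chain. Uniform baselines keep min-max
scaling well-behaved (no outlier compresses the rest of the cohort).

The packaged 4-domain / 14-slice model mirrors the published
pandemic-vulnerability structure (infection rate, population
concentration, intervention measures, health & environment; intervention
components are protective). Its per-slice weights are documented
placeholders — the published model's weights are available only as a
figure — so scores computed from it are structurally, not numerically,
comparable to the published index.

What the simulation does **not** emulate: irregular county geometries and
areas, spatially autocorrelated baseline fields, heavy-tailed or ordinal
components, and missing-data patterns. Passing the planted-cluster tests
therefore demonstrates that the machinery recovers compact elevated
regions under clean conditions, not a sensitivity claim about real
surveillance data.

## Test calibration notes

Planted-cluster recovery is checked on a 12 × 12 lattice, δ = 3 (three
times the baseline component range), cluster radius two cells, band
1.5 × spacing, over 20 fixed seeds; the record nearest the planted center
must reach bin +3 and all four lattice corners stay at |bin| ≤ 1 in at
least 18 of 20 runs. The null check (δ = 0, FDR off, 50 seeds) compares
the pooled share of |bin| ≥ 2 records against the nominal 5% level with a
binomial test at α = 0.01; neighboring Gi* z-scores are positively
correlated, so the pooled count is mildly over-dispersed relative to a
binomial and the test is approximate by construction. These problem sizes
keep the full suite and the acceptance script in the seconds range on a
single CPU.

## Known limitations

- No de-overlapping of neighboring glyphs in dense areas beyond the
  shrunken dense layer; no timescale/animation support.
- The CRS registry ships only the CONUS Albers family; other projections
  require explicit standard parallels.
- Inference is the analytical normal approximation; conditional
  permutation inference and other weight kernels (k-NN, contiguity) are
  out of scope.
- The pre-scored CSV reader defines its own documented schema; exports
  from external scoring GUIs need a one-time column mapping.
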