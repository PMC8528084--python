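# toxpimap

Integrative geographic visual analytics without a GIS vendor lock-in:
compute **ToxPi** (Toxicological Prioritization Index) slice and overall
scores from a component data matrix, draw each record's ToxPi as geolocated
radar-glyph wedge polygons, assemble multi-scale map layers (local, dense,
group-median, choropleth), and find statistically significant spatial
clusters of the score with **Getis-Ord Gi\*** hotspot analysis — all
emitted as standard RFC 7946 GeoJSON that any web map or desktop GIS can
render.

## Who this is for

Public-health and environmental-health analysts who integrate
heterogeneous county- or tract-level indicators (infection rates,
demographics, interventions, pollution, ...) into a single vulnerability
or priority score, and want interactive maps in which every region's glyph
shows not just the combined score but the contribution of each factor
driving it.

## The model and statistics

**ToxPi scoring.** A model groups components into weighted *slices*
(sectors of the radar glyph) inside *domains* (color families). Each
component is min-max scaled over the cohort to [0, 1] (protective,
lower-is-worse components are inverted), components combine into a slice
score `s_i` by weighted mean, and slices combine into the normalized
overall score

```
overall = Σ_i w_i · s_i / Σ_i w_i          s_i, overall ∈ [0, 1]
```

In the glyph, slice *i*'s angular width is `360° · w_i / Σw` and its
radial extent is `s_i · r_max`, drawn in an equal-area projected CRS
(default EPSG:5070) so glyph sizes compare fairly across latitude.

**Hotspot analysis.** For binary distance-band weights over neighborhoods
N(i) (great-circle distance, self included, conventionally a 50-mile
band), the local Getis-Ord statistic

```
Gi*_i = [Σ_j w_ij x_j − X̄ W_i] / (S √[(n·W_i − W_i²)/(n−1)])
```

is a z-score; two-sided normal p-values (Benjamini-Hochberg FDR-adjusted
by default) place each record in a seven-bin confidence class
`Gi_Bin ∈ {−3..+3}`: |bin| 3/2/1 at 99/95/90% confidence, positive for
hotspots, negative for coldspots.

## Worked example

A bundled simulator generates a county-like lattice with a 4-domain /
14-slice pandemic-vulnerability-style model and an optional planted
high-score cluster:

```sh
toxpimap simulate -o demo --seed 7 --effect 3 --cluster
toxpimap hotspot -i demo/data.csv -m demo/model.json -o demo_hs --band-miles 28
```

prints

```
Getis-Ord Gi* hotspot analysis of 'overall'
  records: 144   band: 28.0 mi (45062 m)   FDR (Benjamini-Hochberg): on
  Gi_Bin  confidence        count
      +3  99% hotspot          12
      +2  95% hotspot           1
      +1  90% hotspot           1
      +0  not signif.         130
      -1  90% coldspot          0
      -2  95% coldspot          0
      -3  99% coldspot          0
```

The 12 counties classified `+3` are exactly the lattice cells inside the
planted 60 km cluster: their neighborhoods' overall vulnerability scores
sum significantly higher than spatial randomness allows at 99% confidence.
`demo_hs.csv` holds per-county `gi_z`, `p`, `p_adj` and `bin`;
`demo_hs.geojson` is the same result as a hot-red/cold-blue map layer.

The one-shot pipeline needs only an input file and an output directory
(sibling `model.json`, `boundaries.geojson`, `groups.csv` are discovered
automatically):

```sh
toxpimap run-all -i demo/data.csv -o demo_out
```

which writes six GeoJSON layers — `local_glyphs` (144 × 14 wedge
features), `local_glyphs_dense` (half-radius copy for crowded areas),
`group_glyphs` (state-median glyphs), `local_choropleth` and
`group_choropleth` (quantile-classed overall score), `rings` — each with
a `.style.json` sidecar (role, zoom hints, legend), plus `scores.csv` and
hotspot outputs. The same functionality is available as a library:

```python
import toxpimap as tm

model = tm.pvi_like_model()
matrix, boundaries, groups = tm.generate_lattice(tm.SimSpec(seed=7))
results = tm.score(matrix, model)           # slice scores + overall in [0,1]
fit = tm.HotspotAnalysis(results, band_miles=50).fit()
print(fit.summary())
```

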