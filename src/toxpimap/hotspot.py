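"""Getis-Ord Gi* hotspot analysis of ToxPi scores.

The local Gi* statistic asks, for each record, whether the values in its
neighborhood (itself included) sum higher or lower than expected under a
spatially random arrangement. With binary distance-band weights w_ij over
neighbors N(i),

    Gi*_i = [ sum_j w_ij x_j - Xbar W_i ]
            / ( S * sqrt( [n * W_i - W_i^2] / (n - 1) ) )

where W_i = |N(i)|, Xbar = mean(x), S = sqrt(mean(x^2) - Xbar^2). The
statistic is already a z-score; two-sided normal p-values feed a seven-bin
confidence classification Gi_Bin in {-3..+3}: |bin| 3/2/1 at the 99/95/90%
confidence levels, sign following the z-score, 0 otherwise. An optional
Benjamini-Hochberg FDR correction (on by default) is applied to the
p-values before binning.

Neighborhoods use great-circle (haversine) distance on the WGS84 sphere so
they do not depend on any map projection; the conventional band for US
county data is 50 miles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .scoring import ToxPiResults

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius
METERS_PER_MILE = 1609.344

#: Diverging hot-red / cold-blue palette for the seven Gi_Bin classes -3..+3.
BIN_COLORS = {
    -3: "#2166ac",
    -2: "#67a9cf",
    -1: "#d1e5f0",
    0: "#f7f7f7",
    1: "#fddbc7",
    2: "#ef8a62",
    3: "#b2182b",
}


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters between points in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class SpatialWeights:
    """Binary distance-band neighborhoods (self always included).

    ``neighbors[i]`` holds the indices j with d(i, j) <= band, including i
    itself; the relation is symmetric because the distance is.
    """

    neighbors: tuple[np.ndarray, ...]
    band_m: float

    def __len__(self) -> int:
        return len(self.neighbors)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])


def build_distance_band_weights(lat, lon, band_m: float) -> SpatialWeights:
    """All-pairs haversine thresholding at ``band_m`` meters (inclusive)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    n = lat.size
    if band_m <= 0:
        raise ValidationError("distance band must be > 0")
    if n < 2:
        raise ValidationError("need at least 2 points for spatial weights")
    d = haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    mask = d <= band_m
    neighbors = tuple(np.flatnonzero(mask[i]) for i in range(n))
    isolated = [i for i, nb in enumerate(neighbors) if len(nb) <= 1]
    if isolated:
        logger.warning(
            "%d record(s) have no neighbor within %.0f m (retained)",
            len(isolated), band_m,
        )
    return SpatialWeights(neighbors=neighbors, band_m=float(band_m))


def gi_star(values, weights: SpatialWeights) -> np.ndarray:
    """Gi* z-score for every record under binary weights.

    Degenerate cases — zero global spread, or a neighborhood covering all n
    points so the variance bracket vanishes — yield z = 0 with a warning
    rather than an error.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("Gi* requires at least 2 records")
    if not np.all(np.isfinite(x)):
        raise ValidationError("Gi* input values must be finite")
    if n != len(weights):
        raise ValidationError("values and weights describe different record counts")
    xbar = x.mean()
    s2 = (x * x).mean() - xbar * xbar
    S = np.sqrt(max(s2, 0.0))
    z = np.zeros(n)
    if S == 0.0:
        logger.warning("all values identical; Gi* set to 0 everywhere")
        return z
    degenerate = 0
    for i, nb in enumerate(weights.neighbors):
        Wi = float(len(nb))  # binary weights: sum w = sum w^2 = |N(i)|
        bracket = (n * Wi - Wi * Wi) / (n - 1.0)
        if bracket <= 0.0:
            degenerate += 1
            continue
        z[i] = (x[nb].sum() - xbar * Wi) / (S * np.sqrt(bracket))
    if degenerate:
        logger.warning(
            "%d record(s) neighbor every point; their Gi* set to 0", degenerate
        )
    return z


def z_to_p(z) -> np.ndarray:
    """Two-sided normal p-value of a z-score."""
    return 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def assign_bins(z, p) -> np.ndarray:
    """Seven-bin confidence classification Gi_Bin.

    |bin| = 3 if p <= 0.01 (99% confidence), 2 if p <= 0.05 (95%),
    1 if p <= 0.10 (90%), else 0; the sign follows the z-score. With raw
    normal p-values this reproduces the classic |z| cutoffs
    1.645 / 1.960 / 2.576.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    if z.shape != p.shape:
        raise ValidationError("z and p must have equal length")
    mag = np.where(p <= 0.01, 3, np.where(p <= 0.05, 2, np.where(p <= 0.10, 1, 0)))
    return (mag * np.sign(z)).astype(int)


@dataclass
class HotspotResults:
    """Per-record Gi* output joined to the analysis variable."""

    table: pd.DataFrame  # record_id index; value, gi_z, p, p_adj, bin
    field: str
    band_m: float
    fdr: bool

    def summary(self) -> str:
        t = self.table
        counts = t["bin"].value_counts().reindex(range(-3, 4), fill_value=0)
        lines = [
            f"Getis-Ord Gi* hotspot analysis of {self.field!r}",
            f"  records: {len(t)}   band: {self.band_m / METERS_PER_MILE:.1f} mi "
            f"({self.band_m:.0f} m)   FDR (Benjamini-Hochberg): "
            f"{'on' if self.fdr else 'off'}",
            "  Gi_Bin  confidence        count",
        ]
        label = {3: "99% hotspot ", 2: "95% hotspot ", 1: "90% hotspot ",
                 0: "not signif. ", -1: "90% coldspot", -2: "95% coldspot",
                 -3: "99% coldspot"}
        for b in range(3, -4, -1):
            lines.append(f"  {b:+6d}  {label[b]}      {counts[b]:5d}")
        return "\n".join(lines)


class HotspotAnalysis:
    """Model-like wrapper: configure on data, ``fit()`` returns results.

    Parameters
    ----------
    results : ToxPiResults
        Scored records with WGS84 locations.
    field : str
        ``"overall"`` or any slice name; the variable analyzed.
    band_miles : float
        Neighborhood radius (great-circle), default 50 miles.
    """

    def __init__(self, results: ToxPiResults, field: str = "overall",
                 band_miles: float = 50.0):
        if field != "overall" and field not in results.slice_scores.columns:
            raise ValidationError(
                f"unknown field {field!r}; expected 'overall' or one of "
                f"{list(results.slice_scores.columns)}"
            )
        self.results = results
        self.field = field
        self.band_m = band_miles * METERS_PER_MILE

    def fit(self, fdr: bool = True) -> HotspotResults:
        res = self.results
        x = (res.overall if self.field == "overall"
             else res.slice_scores[self.field]).to_numpy(dtype=float)
        w = build_distance_band_weights(res.lat.to_numpy(), res.lon.to_numpy(),
                                        self.band_m)
        z = gi_star(x, w)
        p = z_to_p(z)
        p_adj = adjust_fdr(p)
        bins = assign_bins(z, p_adj if fdr else p)
        table = pd.DataFrame(
            {
                "value": x,
                "gi_z": z,
                "p": p,
                "p_adj": p_adj,
                "bin": bins,
            },
            index=res.slice_scores.index.rename("record_id"),
        )
        return HotspotResults(table=table, field=self.field,
                              band_m=self.band_m, fdr=fdr)


def hotspot_pipeline(results: ToxPiResults, field: str = "overall",
                     band_miles: float = 50.0, fdr: bool = True) -> pd.DataFrame:
    """End-to-end weights -> Gi* -> (FDR) -> bins; joinable on record_id."""
    return HotspotAnalysis(results, field=field, band_miles=band_miles).fit(fdr=fdr).table
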