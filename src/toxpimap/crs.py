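"""Projected coordinate systems for glyph drawing.

Glyph polygons are drawn with a fixed metric radius, so records must first be
projected from geographic WGS84 coordinates into a planar system in meters.
An equal-area projection keeps glyph sizes visually comparable across
latitude; the default is the CONUS Albers equal-area conic (EPSG:5070).

The forward and inverse Albers transforms on the ellipsoid follow the
closed-form conic equations of Snyder's *Map Projections — A Working Manual*
(USGS PP 1395), with the inverse latitude recovered by Newton iteration on
the authalic-latitude equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CRSError, ValidationError

# GRS80 ellipsoid (EPSG:5070 datum NAD83); WGS84 differs by < 0.1 mm here.
GRS80_A = 6378137.0
GRS80_F = 1.0 / 298.257222101


def _authalic_q(sin_phi: np.ndarray, e: float) -> np.ndarray:
    """Snyder's q: twice the authalic-latitude sine scaled to the ellipsoid."""
    esin = e * sin_phi
    return (1.0 - e * e) * (
        sin_phi / (1.0 - esin * esin)
        - (1.0 / (2.0 * e)) * np.log((1.0 - esin) / (1.0 + esin))
    )


def _m(sin_phi: float, cos_phi: float, e: float) -> float:
    return cos_phi / math.sqrt(1.0 - (e * sin_phi) ** 2)


@dataclass(frozen=True)
class AlbersEqualArea:
    """Albers equal-area conic projection on an ellipsoid of revolution.

    Parameters
    ----------
    lat_1, lat_2 : float
        Standard parallels in degrees. Along these parallels scale is true.
    lat_0, lon_0 : float
        Latitude/longitude of origin in degrees.
    a : float
        Semi-major axis in meters.
    f : float
        Flattening.
    name : str
        Human-readable identifier (e.g. ``"EPSG:5070"``).
    """

    lat_1: float
    lat_2: float
    lat_0: float = 0.0
    lon_0: float = 0.0
    a: float = GRS80_A
    f: float = GRS80_F
    name: str = "albers-custom"

    def __post_init__(self) -> None:
        e2 = self.f * (2.0 - self.f)
        e = math.sqrt(e2)
        phi1 = math.radians(self.lat_1)
        phi2 = math.radians(self.lat_2)
        m1 = _m(math.sin(phi1), math.cos(phi1), e)
        q1 = float(_authalic_q(np.asarray(math.sin(phi1)), e))
        if abs(self.lat_1 - self.lat_2) < 1e-12:
            n = math.sin(phi1)
        else:
            m2 = _m(math.sin(phi2), math.cos(phi2), e)
            q2 = float(_authalic_q(np.asarray(math.sin(phi2)), e))
            n = (m1 * m1 - m2 * m2) / (q2 - q1)
        if abs(n) < 1e-12:
            raise CRSError(
                "degenerate Albers cone (standard parallels symmetric about "
                "the equator); choose asymmetric parallels"
            )
        C = m1 * m1 + n * q1
        q0 = float(_authalic_q(np.asarray(math.sin(math.radians(self.lat_0))), e))
        object.__setattr__(self, "_e", e)
        object.__setattr__(self, "_n", n)
        object.__setattr__(self, "_C", C)
        object.__setattr__(self, "_rho0", self.a * math.sqrt(C - n * q0) / n)

    # -- forward ---------------------------------------------------------
    def project(self, lat, lon):
        """Project WGS84 degrees to planar (x, y) meters.

        Accepts scalars or array-likes; returns numpy scalars/arrays.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
            raise ValidationError("latitude must be in [-90, 90] and longitude in [-180, 180]")
        e, n, C = self._e, self._n, self._C
        q = _authalic_q(np.sin(np.radians(lat)), e)
        rho = self.a * np.sqrt(C - n * q) / n
        theta = n * np.radians(((lon - self.lon_0) + 180.0) % 360.0 - 180.0)
        x = rho * np.sin(theta)
        y = self._rho0 - rho * np.cos(theta)
        return x[()], y[()]

    # -- inverse ---------------------------------------------------------
    def unproject(self, x, y):
        """Invert planar meters back to (lat, lon) WGS84 degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        e, n, C = self._e, self._n, self._C
        dy = self._rho0 - y
        rho = np.hypot(x, dy)
        # for a south-pointing cone (n < 0) the polar angle flips sign
        sgn = 1.0 if n >= 0 else -1.0
        theta = np.arctan2(sgn * x, sgn * dy)
        q = (C - (rho * n / self.a) ** 2) / n
        phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
        one_m_e2 = 1.0 - e * e
        for _ in range(12):  # Newton iteration, quadratic convergence
            s = np.sin(phi)
            esin = e * s
            delta = (
                (1.0 - esin * esin) ** 2
                / (2.0 * np.cos(phi))
                * (
                    q / one_m_e2
                    - s / (1.0 - esin * esin)
                    + (1.0 / (2.0 * e)) * np.log((1.0 - esin) / (1.0 + esin))
                )
            )
            phi = phi + delta
            if np.all(np.abs(delta) < 1e-14):
                break
        lat = np.degrees(phi)
        lon = (self.lon_0 + np.degrees(theta / n) + 180.0) % 360.0 - 180.0
        return lat[()], lon[()]


#: EPSG registry of named projections. 5070 is NAD83 / Conus Albers, the
#: standard equal-area system for the continental United States.
_REGISTRY = {
    5070: AlbersEqualArea(lat_1=29.5, lat_2=45.5, lat_0=23.0, lon_0=-96.0, name="EPSG:5070"),
}


def get_crs(code) -> AlbersEqualArea:
    """Look up a projected CRS by EPSG code (int or ``"EPSG:nnnn"`` string)."""
    if isinstance(code, AlbersEqualArea):
        return code
    if isinstance(code, str):
        token = code.upper().removeprefix("EPSG:")
        try:
            code = int(token)
        except ValueError:
            raise CRSError(f"unrecognized CRS spec {code!r}") from None
    try:
        return _REGISTRY[code]
    except KeyError:
        raise CRSError(
            f"unknown EPSG code {code}; known: {sorted(_REGISTRY)}"
        ) from None
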