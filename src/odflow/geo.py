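"""Coordinate handling: geographic <-> UTM conversion and straight-line distances.

Distances between municipalities are straight lines, either as the Euclidean
norm of UTM (transverse Mercator) plane coordinates or as great-circle
(haversine) arcs.  The UTM forward projection is implemented with the
Krueger series in the third flattening (Karney 2011), which is accurate to
well below a millimetre anywhere inside a zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .records_io import Municipality

__all__ = [
    "GeoPoint",
    "UTMPoint",
    "latlon_to_utm",
    "utm_zone_of",
    "haversine_km",
    "distance_km",
    "GeoError",
]

#: mean Earth radius used for great-circle distances, in kilometres
EARTH_RADIUS_KM = 6371.0088

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

# third flattening and rectifying radius
_N = _F / (2.0 - _F)
_RECTIFYING_A = _A / (1.0 + _N) * (
    1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0
)

# Krueger series coefficients alpha_j (order 6 in the third flattening)
_ALPHA = (
    _N / 2.0 - 2.0 / 3.0 * _N**2 + 5.0 / 16.0 * _N**3
    + 41.0 / 180.0 * _N**4 - 127.0 / 288.0 * _N**5 + 7891.0 / 37800.0 * _N**6,
    13.0 / 48.0 * _N**2 - 3.0 / 5.0 * _N**3 + 557.0 / 1440.0 * _N**4
    + 281.0 / 630.0 * _N**5 - 1983433.0 / 1935360.0 * _N**6,
    61.0 / 240.0 * _N**3 - 103.0 / 140.0 * _N**4
    + 15061.0 / 26880.0 * _N**5 + 167603.0 / 181440.0 * _N**6,
    49561.0 / 161280.0 * _N**4 - 179.0 / 168.0 * _N**5
    + 6601661.0 / 7257600.0 * _N**6,
    34729.0 / 80640.0 * _N**5 - 3418889.0 / 1995840.0 * _N**6,
    212378941.0 / 319334400.0 * _N**6,
)


class GeoError(ValueError):
    """Raised for coordinates outside the domain of an operation."""


@dataclass(frozen=True)
class GeoPoint:
    """A point in geographic coordinates, decimal degrees, WGS84."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise GeoError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise GeoError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class UTMPoint:
    """A point in UTM plane coordinates (metres).

    ``zone`` is the longitudinal zone 1..60 and ``hemisphere`` is ``"N"``
    or ``"S"``.  Eastings far outside the usual 100,000-900,000 m band are
    legal (they arise when a point is forced into a neighbouring zone) but
    flag reduced projection accuracy.
    """

    easting: float
    northing: float
    zone: int
    hemisphere: Literal["N", "S"]

    def __post_init__(self) -> None:
        if not 1 <= self.zone <= 60:
            raise GeoError(f"UTM zone {self.zone} outside [1, 60]")
        if self.hemisphere not in ("N", "S"):
            raise GeoError(f"hemisphere must be 'N' or 'S', got {self.hemisphere!r}")
        if self.northing < 0:
            raise GeoError(f"northing {self.northing} is negative")

    @property
    def in_standard_band(self) -> bool:
        return 100_000.0 <= self.easting <= 900_000.0


def utm_zone_of(lon: float) -> int:
    """Standard UTM zone number for a longitude in decimal degrees."""
    zone = int((lon + 180.0) // 6.0) + 1
    return min(zone, 60)  # lon == 180 wraps into zone 60


def latlon_to_utm(p: GeoPoint, forced_zone: Optional[int] = None) -> UTMPoint:
    """Project a geographic point to UTM (WGS84, k0=0.9996).

    Parameters
    ----------
    p:
        Point to project; ``|lat|`` must be below 84 degrees, the limit of
        the UTM system.
    forced_zone:
        Project into this zone's central meridian even if the point lies
        outside the zone.  Needed to put two points of different zones into
        one planar frame before taking a Euclidean distance.
    """
    if abs(p.lat) >= 84.0:
        raise GeoError(f"latitude {p.lat} outside UTM applicability (|lat| < 84)")
    zone = forced_zone if forced_zone is not None else utm_zone_of(p.lon)
    if not 1 <= zone <= 60:
        raise GeoError(f"UTM zone {zone} outside [1, 60]")

    lon0 = math.radians(-183.0 + 6.0 * zone)  # central meridian
    phi = math.radians(p.lat)
    dlam = math.radians(p.lon) - lon0

    # conformal latitude
    s = (2.0 * math.sqrt(_N)) / (1.0 + _N)
    t = math.sinh(
        math.atanh(math.sin(phi)) - s * math.atanh(s * math.sin(phi))
    )
    xi_p = math.atan2(t, math.cos(dlam))
    eta_p = math.asinh(math.sin(dlam) / math.hypot(t, math.cos(dlam)))

    xi = xi_p
    eta = eta_p
    for j, alpha in enumerate(_ALPHA, start=1):
        xi += alpha * math.sin(2 * j * xi_p) * math.cosh(2 * j * eta_p)
        eta += alpha * math.cos(2 * j * xi_p) * math.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _RECTIFYING_A * eta
    northing = _K0 * _RECTIFYING_A * xi
    hemisphere: Literal["N", "S"] = "N" if p.lat >= 0 else "S"
    if hemisphere == "S":
        northing += _FALSE_NORTHING_SOUTH
    return UTMPoint(easting=easting, northing=northing, zone=zone, hemisphere=hemisphere)


def haversine_km(a: GeoPoint, b: GeoPoint, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two geographic points, in kilometres."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon) - math.radians(a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def distance_km(
    a: "Municipality",
    b: "Municipality",
    method: Literal["utm", "great_circle"] = "utm",
) -> float:
    """Straight-line distance between two municipalities in kilometres.

    With ``method="utm"`` the distance is the Euclidean norm of UTM plane
    coordinates.  Registry-supplied UTM coordinates are used when both
    municipalities carry them in the same zone and hemisphere; otherwise
    both points are projected from lat/lon, forced into the zone of their
    midpoint longitude so that they share one planar frame.  The midpoint
    zone keeps the distance exactly symmetric in its arguments and halves
    the worst-case distance from the central meridian for cross-zone
    pairs.

    With ``method="great_circle"`` the haversine formula on a sphere of
    mean radius 6371.0088 km is used; it needs no zone handling and agrees
    with the UTM distance to well under 0.5% at state scale.
    """
    if method not in ("utm", "great_circle"):
        raise ValueError(f"unknown distance method {method!r}")
    for m in (a, b):
        if m.lat is None or m.lon is None:
            raise GeoError(f"municipality {m.code} has no lat/lon coordinates")
    if a.code == b.code:
        return 0.0

    if method == "great_circle":
        return haversine_km(GeoPoint(a.lat, a.lon), GeoPoint(b.lat, b.lon))

    if (
        a.has_utm
        and b.has_utm
        and a.utm_zone == b.utm_zone
        and a.utm_hemisphere == b.utm_hemisphere
    ):
        de = a.easting - b.easting
        dn = a.northing - b.northing
    else:
        pa = GeoPoint(a.lat, a.lon)
        pb = GeoPoint(b.lat, b.lon)
        zone = utm_zone_of((a.lon + b.lon) / 2.0)
        ua = latlon_to_utm(pa, forced_zone=zone)
        ub = latlon_to_utm(pb, forced_zone=zone)
        de = ua.easting - ub.easting
        dn = ua.northing - ub.northing
    return math.hypot(de, dn) / 1000.0
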