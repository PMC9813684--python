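"""Geographic (latitude/longitude) coordinates for 2D lattices.

The two copies of the quotient triangle QT (positive and negative
chirality), glued along their common boundary of mirror-symmetric
lattices, form a punctured sphere.  This module realises that picture
literally: the incentre P+ of QT becomes the north pole, the boundary
∂QT becomes the equator, and every lattice receives a latitude
φ ∈ [-90°, 90°] and a longitude μ ∈ (-180°, 180°].

Conventions
-----------
* The incentre of the right isosceles triangle (0,0), (1,0), (0,1) sits
  at (t, t) with t = 1 - 1/√2; it is the unique interior point whose
  rays to the three vertices bisect the angles 90°, 45°, 45°.
* The Greenwich point G = (0, √2 - 1) is where the line through the
  incentre and the excluded vertex (1, 0) meets the edge x = 0; the
  meridian through G has longitude 0.  Seen from the incentre, G lies
  at planar bearing 157.5°.
* Latitude is linear along each ray from the incentre: φ = ±90° at the
  incentre (north/south pole by chirality sign), 0° on ∂QT.
* Points on the open segment from (1, 0) to the incentre receive
  longitude +180° rather than -180° (half-open wrap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .invariants import ProjectedInvariant, RootInvariant, projected_invariant
from .lattice_core import LatticeError

__all__ = [
    "INCENTRE_T",
    "GREENWICH_POINT",
    "GREENWICH_BEARING",
    "SphereCoord",
    "UndefinedLongitudeError",
    "bearing",
    "longitude",
    "boundary_hit",
    "latitude",
    "spherical_map",
    "greenwich_ratio",
]

#: Incentre coordinate t = 1 - 1/√2 of the triangle (0,0), (1,0), (0,1);
#: the inradius is (2 - √2)/2 = t.
INCENTRE_T = 1.0 - 1.0 / math.sqrt(2.0)

#: Greenwich point on the edge x = 0, on the line through (t, t) and (1, 0).
GREENWICH_POINT = (0.0, math.sqrt(2.0) - 1.0)

#: Planar bearing (degrees) of the Greenwich point seen from the incentre.
GREENWICH_BEARING = 157.5


class UndefinedLongitudeError(LatticeError):
    """The projected invariant is the incentre: a pole, no longitude."""


@dataclass(frozen=True)
class SphereCoord:
    """Latitude φ ∈ [-90, 90] and longitude μ ∈ (-180, 180] in degrees.

    ``defined_longitude`` is False exactly at the poles (|φ| = 90), where
    every meridian meets; the stored longitude is then a placeholder 0.
    """

    latitude: float
    longitude: float
    defined_longitude: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise LatticeError("latitude out of range")
        if self.defined_longitude and not -180.0 < self.longitude <= 180.0:
            raise LatticeError("longitude out of range")


def _is_incentre(pi: ProjectedInvariant, tol: float = 1e-12) -> bool:
    return abs(pi.x - INCENTRE_T) <= tol and abs(pi.y - INCENTRE_T) <= tol


def bearing(pi: ProjectedInvariant) -> float:
    """Planar angle (degrees, in (-180, 180]) of (x, y) seen from the incentre.

    atan2 of (y - t, x - t); for x = t exactly this is sign(y - t) * 90°.
    Undefined at the incentre itself.
    """
    if _is_incentre(pi):
        raise UndefinedLongitudeError("bearing undefined at the incentre")
    return math.degrees(math.atan2(pi.y - INCENTRE_T, pi.x - INCENTRE_T))


def _wrap_longitude(mu: float) -> float:
    """Wrap an angle in degrees into the half-open interval (-180, 180]."""
    mu = math.fmod(mu, 360.0)
    if mu <= -180.0:
        mu += 360.0
    elif mu > 180.0:
        mu -= 360.0
    return mu


def _on_antimeridian_segment(pi: ProjectedInvariant, tol: float = 1e-9) -> bool:
    """True on the open segment from (1, 0) to the incentre (t, t)."""
    if pi.x <= INCENTRE_T:
        return False
    # collinearity with (t, t) -> (1, 0): cross product of offsets
    cross = (pi.x - INCENTRE_T) * (0.0 - INCENTRE_T) - (pi.y - INCENTRE_T) * (1.0 - INCENTRE_T)
    return abs(cross) <= tol


def longitude(pi: ProjectedInvariant) -> float:
    """Longitude μ ∈ (-180°, 180°]: bearing measured from the Greenwich meridian.

    μ = wrap(bearing - 157.5°).  Points on the open segment from the
    excluded vertex (1, 0) to the incentre sit on the antimeridian and
    receive +180° exactly.
    """
    if _on_antimeridian_segment(pi):
        return 180.0
    return _wrap_longitude(bearing(pi) - GREENWICH_BEARING)


def boundary_hit(pi: ProjectedInvariant) -> tuple[float, float]:
    """Intersection of the ray incentre -> (x, y) with the boundary of QT.

    The ray parameter is the smallest positive solution over the three
    edge lines x = 0, y = 0 and x + y = 1.
    """
    if _is_incentre(pi):
        raise UndefinedLongitudeError("no boundary ray from the incentre itself")
    t = INCENTRE_T
    dx, dy = pi.x - t, pi.y - t
    candidates = []
    if dx < 0.0:
        candidates.append(-t / dx)          # edge x = 0
    if dy < 0.0:
        candidates.append(-t / dy)          # edge y = 0
    if dx + dy > 0.0:
        candidates.append((1.0 - 2.0 * t) / (dx + dy))  # hypotenuse
    s = min(candidates)
    return (t + s * dx, t + s * dy)


def latitude(pi: ProjectedInvariant) -> float:
    """Latitude φ ∈ [-90°, 90°], linear along rays from the incentre.

    With s the fractional position of (x, y) between the incentre (s = 0)
    and its boundary hit (s = 1): φ = sign * 90° * (1 - s).  Mirror-
    symmetric lattices (sign = 0) lie on ∂QT and get φ = 0; the incentre
    with sign ±1 is the north/south pole.
    """
    if pi.sign == 0:
        if not pi.on_boundary(tol=1e-7):
            raise LatticeError(
                "sign = 0 requires the projected invariant on the boundary of QT"
            )
        return 0.0
    if _is_incentre(pi):
        return 90.0 * pi.sign
    t = INCENTRE_T
    hx, hy = boundary_hit(pi)
    s = math.hypot(pi.x - t, pi.y - t) / math.hypot(hx - t, hy - t)
    return pi.sign * 90.0 * (1.0 - min(s, 1.0))


def spherical_map(pi: ProjectedInvariant) -> SphereCoord:
    """Full geographic coordinates of a lattice from its projected invariant.

    Positive-chirality lattices land on the northern hemisphere, negative
    on the southern, mirror-symmetric ones on the equator.  The incentre
    maps to a pole, where the longitude is undefined.
    """
    phi = latitude(pi)
    if _is_incentre(pi):
        return SphereCoord(latitude=phi, longitude=0.0, defined_longitude=False)
    return SphereCoord(latitude=phi, longitude=longitude(pi))


def greenwich_ratio() -> float:
    """Side ratio b/a of the centred rectangular lattices at the Greenwich point.

    A centred rectangular lattice with conventional cell 2a × 2b (b < a√3)
    has root invariant (√(b² - a²), a√2, a√2) and projects onto the edge
    x = 0 of QT.  The Greenwich point G = (0, √2 - 1) therefore fixes a
    unique ratio, found here by solving y(b/a) = √2 - 1 numerically.
    """
    target = GREENWICH_POINT[1]

    def f(ratio: float) -> float:
        r12 = math.sqrt(ratio * ratio - 1.0)
        ri = RootInvariant(*sorted((r12, math.sqrt(2.0), math.sqrt(2.0))))
        return projected_invariant(ri).y - target

    return brentq(f, 1.0 + 1e-9, math.sqrt(3.0) - 1e-9, xtol=1e-12)
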