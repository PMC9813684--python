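"""Complete continuous invariants of 2D lattices.

The *root invariant* RI = (r12, r01, r02) collects the square roots of the
conorms of the (unique up to isometry) obtuse superbase, ordered
ascending.  It is a complete isometry invariant: two lattices are
isometric exactly when their root invariants agree.  Adding the chirality
``sign`` upgrades it to a complete invariant up to rigid motion.

Dividing by the *size* σ = r12 + r01 + r02 removes scale and projects RI
into the quotient triangle QT — the right isosceles triangle with
vertices (0,0), (1,0), (0,1) — via

    x = (r02 - r01) / σ,      y = 3 r12 / σ.

The boundary of QT carries exactly the mirror-symmetric lattices: y = 0
are rectangular lattices, x = 0 and the hypotenuse x + y = 1 are centred
rectangular, the vertex (0,0) is square and (0,1) hexagonal.  Interior
points are oblique lattices, which occur in chiral pairs distinguished by
``sign``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .lattice_core import (
    DegenerateLatticeError,
    LatticeError,
    ObtuseSuperbase,
    ReducedCell,
)

__all__ = [
    "RootInvariant",
    "OrientedRootInvariant",
    "ProjectedInvariant",
    "QuadraticInvariant",
    "root_invariant",
    "lattice_sign",
    "size",
    "projected_invariant",
    "quadratic_invariant",
    "ri_distance",
    "dissymmetry",
]

#: Default relative tolerance for deciding mirror symmetry from near-equal
#: root products.  Kept tight on purpose: experimental cells that are only
#: approximately rectangular should stay oblique unless the caller opts in
#: to a coarser tolerance.
SYM_TOL = 1e-9


@dataclass(frozen=True)
class RootInvariant:
    """Ordered root products (r12, r01, r02), in Å."""

    r12: float
    r01: float
    r02: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r12 <= self.r01 <= self.r02):
            raise LatticeError(f"root invariant must be ordered, got {self.as_tuple()}")
        if self.r01 <= 0.0:
            raise DegenerateLatticeError("r01 must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r12, self.r01, self.r02)


@dataclass(frozen=True)
class OrientedRootInvariant:
    """Root invariant with the chirality sign: complete up to rigid motion."""

    ri: RootInvariant
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise LatticeError("sign must be -1, 0 or +1")


@dataclass(frozen=True)
class ProjectedInvariant:
    """Scale-free coordinates (x, y) in the quotient triangle QT, plus sign.

    sign = 0 exactly on the boundary of QT (mirror-symmetric lattices).
    """

    x: float
    y: float
    sign: int = 0

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (-eps <= self.x < 1.0 and -eps <= self.y <= 1.0 + eps
                and self.x + self.y <= 1.0 + eps):
            raise LatticeError(f"({self.x}, {self.y}) lies outside the quotient triangle")
        if self.sign not in (-1, 0, 1):
            raise LatticeError("sign must be -1, 0 or +1")

    def on_boundary(self, tol: float = 1e-9) -> bool:
        return self.x <= tol or self.y <= tol or self.x + self.y >= 1.0 - tol


@dataclass(frozen=True)
class QuadraticInvariant:
    """Homogenised metric tensor (τ11, τ12, τ22) = (√q11, √(-q12), √q22), Å."""

    tau11: float
    tau12: float
    tau22: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau11 <= self.tau22 * (1 + 1e-12)) or self.tau12 < 0.0:
            raise LatticeError("quadratic invariant must satisfy 0 <= tau11 <= tau22, tau12 >= 0")


# ---------------------------------------------------------------------------
# invariants from the canonical superbase
# ---------------------------------------------------------------------------

def root_invariant(sb: ObtuseSuperbase) -> RootInvariant:
    """Square roots of the conorms, ordered ascending.

    The canonical length order |v1| <= |v2| <= |v0| of the superbase makes
    the conorm triple (p12, p01, p02) already ascending.
    """
    p12, p01, p02 = (max(p, 0.0) for p in sb.conorms)
    r = sorted((math.sqrt(p12), math.sqrt(p01), math.sqrt(p02)))
    return RootInvariant(*r)


def lattice_sign(sb: ObtuseSuperbase, tol: float = SYM_TOL) -> int:
    """Chirality sign: 0 for mirror-symmetric lattices, else ±1.

    A lattice is mirror-symmetric exactly when its root products are not
    all distinct or the smallest vanishes (the projected invariant then
    lies on the boundary of QT).  Otherwise the three superbase vectors
    have pairwise distinct lengths; with |v1| < |v2| < |v0| the sign of
    det[v1 v2] is a rigid-motion invariant flipped by reflections.
    """
    ri = root_invariant(sb)
    sigma = ri.r12 + ri.r01 + ri.r02
    if (ri.r12 <= tol * sigma
            or abs(ri.r01 - ri.r12) <= tol * sigma
            or abs(ri.r02 - ri.r01) <= tol * sigma):
        return 0
    d = float(sb.v1[0] * sb.v2[1] - sb.v1[1] * sb.v2[0])
    return 1 if d > 0 else -1


def oriented_root_invariant(sb: ObtuseSuperbase, tol: float = SYM_TOL) -> OrientedRootInvariant:
    """Root invariant plus chirality sign (complete up to rigid motion)."""
    return OrientedRootInvariant(root_invariant(sb), lattice_sign(sb, tol))


def size(ri: RootInvariant) -> float:
    """Size σ = r12 + r01 + r02 — the scale factor removed by projection."""
    return ri.r12 + ri.r01 + ri.r02


def projected_invariant(ri: RootInvariant, sign: int = 0) -> ProjectedInvariant:
    """Project a root invariant into the quotient triangle QT.

    With normalised components r̄ = ri/σ the coordinates are
    x = r̄02 - r̄01 and y = 3 r̄12; scale-invariant by construction.
    """
    sigma = size(ri)
    x = (ri.r02 - ri.r01) / sigma
    y = 3.0 * ri.r12 / sigma
    return ProjectedInvariant(x=x, y=min(y, 1.0), sign=sign)


def quadratic_invariant(rc: ReducedCell) -> QuadraticInvariant:
    """Homogenised metric tensor of the reduced cell.

    The reduced (non-acute) form has q11 = a², q22 = b² and
    q12 = a b cos γ <= 0; taking square roots gives a triple in the same
    length units as the basis coordinates.
    """
    q12 = rc.a * rc.b * math.cos(math.radians(rc.gamma))
    return QuadraticInvariant(rc.a, math.sqrt(max(-q12, 0.0)), rc.b)


# ---------------------------------------------------------------------------
# distances in invariant space
# ---------------------------------------------------------------------------

def ri_distance(a: RootInvariant, b: RootInvariant) -> float:
    """Chebyshev (L∞) distance between two root invariants, in Å."""
    return max(abs(a.r12 - b.r12), abs(a.r01 - b.r01), abs(a.r02 - b.r02))


def _dist_point_segment(p: tuple[float, float],
                        a: tuple[float, float],
                        b: tuple[float, float]) -> float:
    """Euclidean distance from point p to the segment [a, b]."""
    px, py = p
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    t = ((px - ax) * dx + (py - ay) * dy) / (dx * dx + dy * dy)
    t = min(1.0, max(0.0, t))
    cx, cy = ax + t * dx, ay + t * dy
    return math.hypot(px - cx, py - cy)


def dissymmetry(pi: ProjectedInvariant) -> dict[str, float]:
    """Distance from a projected invariant to each higher-symmetry subspace.

    Euclidean distances in QT coordinates to the square vertex (0,0) [tp],
    the hexagonal vertex (0,1) [hp], the rectangular edge y = 0 [op], and
    the centred-rectangular locus {x = 0} ∪ {x + y = 1} [oc].  Each
    distance vanishes exactly on its subspace, giving a continuous measure
    of how far the lattice is from acquiring that symmetry.
    """
    p = (pi.x, pi.y)
    return {
        "tp": math.hypot(pi.x, pi.y),
        "hp": math.hypot(pi.x, pi.y - 1.0),
        "op": _dist_point_segment(p, (0.0, 0.0), (1.0, 0.0)),
        "oc": min(_dist_point_segment(p, (0.0, 0.0), (0.0, 1.0)),
                  _dist_point_segment(p, (1.0, 0.0), (0.0, 1.0))),
    }
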