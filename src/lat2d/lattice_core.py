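"""Lattice representations and obtuse-superbase (Selling/Delaunay) reduction.

A two-dimensional lattice is the set of integer combinations of two
independent plane vectors.  Every such lattice has an *obtuse superbase*:
a vector triple ``v0, v1, v2`` with ``v0 + v1 + v2 = 0`` whose pairwise
scalar products are all non-positive, i.e. whose conorms
``p_ij = -v_i . v_j`` are all non-negative.  The obtuse superbase is unique
up to isometry, which makes it the natural canonical form from which
continuous, complete invariants are computed (see :mod:`lat2d.invariants`).

This module provides:

* the raw containers :class:`Basis2D`, :class:`Cell2D`, :class:`Cell3D`,
* :func:`selling_reduce` — the reduction of an arbitrary basis to a
  canonical :class:`ObtuseSuperbase`,
* :func:`reduced_cell` — the non-acute reduced cell read off a superbase,
* :func:`reconstruct_from_RI` — inverse design of a basis realising a
  prescribed root invariant and chirality sign.

All lengths are in ångströms and angles in degrees unless noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .invariants import RootInvariant

__all__ = [
    "LatticeError",
    "DegenerateLatticeError",
    "Basis2D",
    "Cell2D",
    "Cell3D",
    "ObtuseSuperbase",
    "ReducedCell",
    "cell_to_basis",
    "basis3d_from_cell",
    "selling_reduce",
    "reduced_cell",
    "reconstruct_from_RI",
]

#: Relative tolerance used for the "acute pair" test in the Selling loop,
#: scaled by the largest squared vector norm so right angles do not cycle.
ACUTE_REL_TOL = 1e-12

#: Iteration cap for the Selling loop.  The vector-norm sum strictly
#: decreases each step, so the cap only guards floating-point pathologies.
MAX_SELLING_ITER = 10_000


class LatticeError(ValueError):
    """Invalid lattice input (degenerate cell, unrealisable angles...)."""


class DegenerateLatticeError(LatticeError):
    """The given vectors or parameters do not span a genuine lattice."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Basis2D:
    """Two independent plane vectors spanning a lattice (Å)."""

    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        v1 = np.asarray(self.v1, dtype=float)
        v2 = np.asarray(self.v2, dtype=float)
        object.__setattr__(self, "v1", v1)
        object.__setattr__(self, "v2", v2)
        if v1.shape != (2,) or v2.shape != (2,):
            raise LatticeError("basis vectors must be 2-vectors")
        if not (np.isfinite(v1).all() and np.isfinite(v2).all()):
            raise LatticeError("basis vectors must be finite")
        if self.det == 0.0:
            raise DegenerateLatticeError("collinear basis vectors")

    @property
    def det(self) -> float:
        """Signed determinant of the column matrix [v1 v2]."""
        return float(self.v1[0] * self.v2[1] - self.v1[1] * self.v2[0])

    @property
    def cell_area(self) -> float:
        """Primitive-cell area |det|."""
        return abs(self.det)


@dataclass(frozen=True)
class Cell2D:
    """Parameter form of a 2D primitive cell: side lengths and angle."""

    a: float
    b: float
    gamma: float  # degrees

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise LatticeError(f"cell lengths must be positive, got {self.a}, {self.b}")
        if not (0.0 < self.gamma < 180.0):
            raise LatticeError(f"cell angle must lie in (0, 180), got {self.gamma}")


@dataclass(frozen=True)
class Cell3D:
    """A 3D unit cell given by lengths a, b, c (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    id: str = ""

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise LatticeError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not (0.0 < ang < 180.0):
                raise LatticeError(f"cell angle {name} must lie in (0, 180)")
        ca, cb, cg = (math.cos(math.radians(getattr(self, n)))
                      for n in ("alpha", "beta", "gamma"))
        # Gram determinant of the three unit direction vectors; must be
        # positive for the angle triple to be realisable in 3D.
        gram = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if gram <= 0.0:
            raise LatticeError(
                f"angles ({self.alpha}, {self.beta}, {self.gamma}) do not admit a 3D cell"
            )


@dataclass(frozen=True)
class ObtuseSuperbase:
    """Canonical obtuse superbase: v0 + v1 + v2 = 0, all conorms >= 0.

    Vectors are stored in length order ``|v1| <= |v2| <= |v0|`` so the
    conorms come out ordered ``p12 <= p01 <= p02``.
    """

    v0: np.ndarray
    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        v0 = np.asarray(self.v0, dtype=float)
        v1 = np.asarray(self.v1, dtype=float)
        v2 = np.asarray(self.v2, dtype=float)
        object.__setattr__(self, "v0", v0)
        object.__setattr__(self, "v1", v1)
        object.__setattr__(self, "v2", v2)
        scale = max(float(v @ v) for v in (v0, v1, v2))
        if scale == 0.0:
            raise DegenerateLatticeError("zero superbase")
        tol = 1e-9 * math.sqrt(scale)
        if not np.allclose(v0 + v1 + v2, 0.0, atol=tol):
            raise LatticeError("superbase vectors must sum to zero")
        ptol = ACUTE_REL_TOL * scale
        if min(self.conorms) < -ptol:
            raise LatticeError("superbase is not obtuse")

    @property
    def p12(self) -> float:
        return float(-self.v1 @ self.v2)

    @property
    def p01(self) -> float:
        return float(-self.v0 @ self.v1)

    @property
    def p02(self) -> float:
        return float(-self.v0 @ self.v2)

    @property
    def conorms(self) -> tuple[float, float, float]:
        """(p12, p01, p02) — negative pairwise scalar products."""
        return (self.p12, self.p01, self.p02)


@dataclass(frozen=True)
class ReducedCell:
    """Non-acute reduced cell (a <= b, gamma in [90, 180)) plus chirality sign."""

    a: float
    b: float
    gamma: float
    sign: int

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.b * (1 + 1e-12)):
            raise LatticeError("reduced cell requires 0 < a <= b")
        if not (90.0 - 1e-9 <= self.gamma < 180.0):
            raise LatticeError("reduced cell angle must be non-acute and < 180")
        if self.sign not in (-1, 0, 1):
            raise LatticeError("sign must be -1, 0 or +1")


# ---------------------------------------------------------------------------
# cell -> basis embeddings
# ---------------------------------------------------------------------------

def cell_to_basis(cell: Cell2D) -> Basis2D:
    """Embed a 2D cell with the first vector on +x and positive-y second vector.

    Returns ``v1 = (a, 0)``, ``v2 = (b cos γ, b sin γ)`` with ``sin γ > 0``,
    i.e. a right-handed embedding.  This convention fixes the chirality of
    lattices described only by cell parameters.
    """
    g = math.radians(cell.gamma)
    v1 = np.array([cell.a, 0.0])
    v2 = np.array([cell.b * math.cos(g), cell.b * math.sin(g)])
    return Basis2D(v1, v2)


def basis3d_from_cell(cell: Cell3D) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard crystallographic orthogonalisation of (a, b, c, α, β, γ).

    v1 lies along +x, v2 in the xy-plane with positive y-component, and v3
    completes a right-handed triple; |v1| = a, |v2| = b, |v3| = c and the
    pairwise angles are α between (v2, v3), β between (v1, v3), γ between
    (v1, v2).
    """
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    v1 = np.array([cell.a, 0.0, 0.0])
    v2 = np.array([cell.b * cg, cell.b * sg, 0.0])
    v3x = cell.c * cb
    v3y = cell.c * (ca - cb * cg) / sg
    z2 = cell.c * cell.c - v3x * v3x - v3y * v3y
    if z2 <= 0.0:
        raise LatticeError("angle triple not realisable (non-positive z-component)")
    v3 = np.array([v3x, v3y, math.sqrt(z2)])
    return v1, v2, v3


# ---------------------------------------------------------------------------
# Selling reduction
# ---------------------------------------------------------------------------

def _canonical_order(
    vecs: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order a superbase triple so |v1| <= |v2| <= |v0|.

    Ties in length are broken by the conorm triple of the resulting
    labelling, lexicographically; remaining ties are genuine symmetries.
    """
    best = None
    best_key = None
    for i, j, k in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        w1, w2, w0 = vecs[i], vecs[j], vecs[k]
        n1, n2, n0 = (float(w @ w) for w in (w1, w2, w0))
        if not (n1 <= n2 * (1 + 1e-12) and n2 <= n0 * (1 + 1e-12)):
            continue
        key = (n1, n2, float(-w1 @ w2), float(-w0 @ w1), float(-w0 @ w2))
        if best_key is None or key < best_key:
            best_key = key
            best = (w0, w1, w2)
    assert best is not None
    return best


def selling_reduce(basis: Basis2D) -> ObtuseSuperbase:
    """Reduce a basis to the canonical obtuse superbase of the same lattice.

    Starting from the superbase ``(v1, v2, v0 = -v1 - v2)``, any acute pair
    ``v_i . v_j > 0`` is repaired by ``v_i -> -v_i``, ``v_k -> v_k + 2 v_i``
    (third index k, ``v_j`` kept).  Each step keeps the zero sum, changes the
    basis by a unimodular transform, and strictly decreases
    ``|v0|² + |v1|² + |v2|²`` by ``4 v_i . v_j``, so the loop terminates.

    Pairs are scanned in the fixed order (1,2), (0,1), (0,2) and the first
    acute pair is repaired, which makes runs bit-reproducible.
    """
    vecs = [-basis.v1 - basis.v2, basis.v1.copy(), basis.v2.copy()]  # v0, v1, v2
    pairs = ((1, 2, 0), (0, 1, 2), (0, 2, 1))
    for _ in range(MAX_SELLING_ITER):
        tol = ACUTE_REL_TOL * max(float(v @ v) for v in vecs)
        for i, j, k in pairs:
            dot = float(vecs[i] @ vecs[j])
            if dot > tol:
                vecs[k] = vecs[k] + 2.0 * vecs[i]
                vecs[i] = -vecs[i]
                break
        else:
            v0, v1, v2 = _canonical_order(vecs)
            return ObtuseSuperbase(v0, v1, v2)
    raise RuntimeError(
        "Selling reduction failed to converge; this indicates a floating-point pathology"
    )


def reduced_cell(sb: ObtuseSuperbase) -> ReducedCell:
    """Read the non-acute reduced cell off a canonical obtuse superbase.

    ``a = |v1|``, ``b = |v2|`` and ``γ = angle(v1, v2) ∈ [90°, 180°)`` since
    the pair conorm p12 is non-negative.  The chirality sign is copied from
    :func:`lat2d.invariants.lattice_sign`, giving the rigid-motion
    representative (a, b, γ, sign).
    """
    from .invariants import lattice_sign

    a = float(np.linalg.norm(sb.v1))
    b = float(np.linalg.norm(sb.v2))
    cosg = float(sb.v1 @ sb.v2) / (a * b)
    cosg = min(1.0, max(-1.0, cosg))
    gamma = math.degrees(math.acos(cosg))
    return ReducedCell(a=a, b=b, gamma=max(gamma, 90.0), sign=lattice_sign(sb))


# ---------------------------------------------------------------------------
# inverse design
# ---------------------------------------------------------------------------

def reconstruct_from_RI(ri: "RootInvariant", sign: int = 0) -> Basis2D:
    """Build a basis whose lattice realises the given root invariant and sign.

    With conorms ``p_ij = r_ij²`` the vector lengths follow from
    ``|v1|² = p12 + p01`` and ``|v2|² = p12 + p02``; placing v1 on the +x
    axis and solving ``v1 . v2 = -p12`` fixes v2 up to the sign of its
    y-component, which encodes the chirality.  Round trip:
    ``selling_reduce(reconstruct_from_RI(ri, s))`` reproduces ``(ri, s)``.
    """
    r12, r01, r02 = ri.r12, ri.r01, ri.r02
    if r01 <= 0.0:
        raise DegenerateLatticeError("r01 must be positive for a genuine lattice")
    p12, p01, p02 = r12 * r12, r01 * r01, r02 * r02
    len1 = math.sqrt(p12 + p01)
    len2 = math.sqrt(p12 + p02)
    x2 = -p12 / len1
    h2 = len2 * len2 - x2 * x2
    if h2 <= 0.0:
        raise DegenerateLatticeError("root invariant does not define a planar lattice")
    h = math.sqrt(h2)
    if sign == -1:
        h = -h
    return Basis2D(np.array([len1, 0.0]), np.array([x2, h]))
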