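"""Synthetic lattice and unit-cell generators with ground-truth labels.

Every stage of the package is testable without any external database:
this module generates 2D lattice bases from each Bravais family together
with their *closed-form* root invariants and chirality signs (derived
directly from explicitly obtuse superbases, independently of the Selling
reduction under test), random unimodular re-basings to exercise
invariance, and tables of 3D unit cells emulating the heterogeneous
collections found in crystal-structure databases.

All draws go through a single explicitly seeded NumPy generator, so the
same spec always reproduces the same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice_core import Basis2D, Cell3D, LatticeError

__all__ = [
    "GeneratorSpec",
    "LabelledBasis",
    "make_family",
    "random_unimodular",
    "make_cell_table",
]

FAMILIES = ("square", "hexagonal", "rectangular", "centred_rectangular",
            "oblique", "mixed")

#: Guard band keeping random oblique lattices away from mirror-symmetric
#: loci, so their ground-truth signs are unambiguous.
SYMMETRY_GUARD = 1e-6


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible recipe for a batch of labelled lattice bases.

    ``a_range`` bounds the primary length draw (Å); ``ratio_range`` bounds
    b/a for the two-parameter families.  ``mirror_pairs`` makes the oblique
    family emit reflected pairs with equal RI and opposite signs (and is
    ignored for achiral families).  ``scramble`` applies a random rotation
    and unimodular re-basing to every output, which changes the basis but
    never the lattice; it is off by default because any floating-point
    rotation perturbs exact-zero conorms at the square-root-of-roundoff
    level (~1e-8), which matters when ground truth is compared at 1e-9.
    """

    family: str
    n: int
    seed: int
    a_range: tuple[float, float] = (1.0, 10.0)
    ratio_range: tuple[float, float] = (1.1, 2.5)
    mirror_pairs: bool = False
    scramble: bool = False
    max_shears: int = 4

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise LatticeError(f"unknown family {self.family!r}")
        if self.n < 0:
            raise LatticeError("n must be non-negative")
        if not (0 < self.a_range[0] < self.a_range[1]):
            raise LatticeError("invalid a_range")
        if not (1.0 < self.ratio_range[0] < self.ratio_range[1]):
            raise LatticeError("ratio_range must satisfy 1 < lo < hi")


@dataclass(frozen=True)
class LabelledBasis:
    """A generated basis with its ground truth, computed in closed form."""

    basis: Basis2D
    label: str                       # true Bravais class
    ri_true: tuple[float, float, float]
    sign_true: int


def random_unimodular(rng: np.random.Generator | int, k: int = 4) -> np.ndarray:
    """Random 2x2 integer matrix with determinant exactly ±1.

    Built as a product of ``k`` random elementary shears and swaps, so the
    determinant is ±1 by construction (no floating-point rounding).
    ``k = 0`` returns the identity.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = np.eye(2, dtype=np.int64)
    for _ in range(k):
        kind = rng.integers(0, 3)
        if kind == 0:    # shear on rows
            s = int(rng.choice((-1, 1)))
            e = np.array([[1, s], [0, 1]], dtype=np.int64)
        elif kind == 1:  # shear on columns
            s = int(rng.choice((-1, 1)))
            e = np.array([[1, 0], [s, 1]], dtype=np.int64)
        else:            # swap (determinant -1)
            e = np.array([[0, 1], [1, 0]], dtype=np.int64)
        m = m @ e
    return m


def _rotation(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * math.pi)
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _scrambled(basis: Basis2D, rng: np.random.Generator, k: int) -> Basis2D:
    """Apply a random rotation and unimodular re-basing; the lattice —
    hence every ground-truth invariant — is unchanged."""
    m = random_unimodular(rng, int(rng.integers(1, k + 1)))
    r = _rotation(rng)
    cols = np.column_stack((basis.v1, basis.v2)) @ m
    cols = r @ cols
    return Basis2D(cols[:, 0], cols[:, 1])


def _one_sample(family: str, rng: np.random.Generator,
                spec: GeneratorSpec) -> list[LabelledBasis]:
    a = float(rng.uniform(*spec.a_range))
    if family == "square":
        basis = Basis2D(np.array([a, 0.0]), np.array([0.0, a]))
        return [LabelledBasis(basis, "tp", (0.0, a, a), 0)]
    if family == "hexagonal":
        basis = Basis2D(np.array([a, 0.0]), np.array([-a / 2.0, a * math.sqrt(3.0) / 2.0]))
        r = a / math.sqrt(2.0)
        return [LabelledBasis(basis, "hp", (r, r, r), 0)]
    if family == "rectangular":
        b = a * float(rng.uniform(*spec.ratio_range))
        basis = Basis2D(np.array([a, 0.0]), np.array([0.0, b]))
        return [LabelledBasis(basis, "op", (0.0, a, b), 0)]
    if family == "centred_rectangular":
        # conventional cell 2a x 2b; superbase (2a,0), (-a,b), (-a,-b);
        # conorms (b^2 - a^2, 2a^2, 2a^2).  Avoid b/a = sqrt(3) (hexagonal)
        # and b/a = 1 (square).
        while True:
            ratio = float(rng.uniform(*spec.ratio_range))
            if abs(ratio - math.sqrt(3.0)) > 1e-3:
                break
        b = a * ratio
        basis = Basis2D(np.array([2.0 * a, 0.0]), np.array([-a, b]))
        ri = tuple(sorted((math.sqrt(b * b - a * a), a * math.sqrt(2.0), a * math.sqrt(2.0))))
        return [LabelledBasis(basis, "oc", ri, 0)]
    if family == "oblique":
        return _oblique_sample(a, rng, spec)
    raise AssertionError(family)


def _oblique_sample(a: float, rng: np.random.Generator,
                    spec: GeneratorSpec) -> list[LabelledBasis]:
    """Generic lattice with a strictly obtuse superbase and distinct root
    products; ground truth follows from direct dot products."""
    while True:
        b = a * float(rng.uniform(*spec.ratio_range))
        # gamma < arccos(-a / 2b) keeps |v0| > |v2| (canonical order holds
        # for the constructed superbase without re-sorting).
        gmax = math.degrees(math.acos(-a / (2.0 * b)))
        gamma = float(rng.uniform(90.0 + 0.5, gmax - 0.5))
        g = math.radians(gamma)
        v1 = np.array([a, 0.0])
        v2 = np.array([b * math.cos(g), b * math.sin(g)])
        v0 = -v1 - v2
        p12, p01, p02 = float(-v1 @ v2), float(-v0 @ v1), float(-v0 @ v2)
        if min(p12, p01, p02) <= 0.0:
            continue
        r = sorted(math.sqrt(p) for p in (p12, p01, p02))
        scale = r[0] + r[1] + r[2]
        if (r[0] < SYMMETRY_GUARD * scale
                or r[1] - r[0] < SYMMETRY_GUARD * scale
                or r[2] - r[1] < SYMMETRY_GUARD * scale):
            continue  # too close to a mirror-symmetric locus
        ri = (r[0], r[1], r[2])
        out = [LabelledBasis(Basis2D(v1, v2), "mp", ri, +1)]
        if spec.mirror_pairs:
            refl = np.array([1.0, -1.0])
            out.append(LabelledBasis(Basis2D(v1 * refl, v2 * refl), "mp", ri, -1))
        elif rng.uniform() < 0.5:
            refl = np.array([1.0, -1.0])
            out = [LabelledBasis(Basis2D(v1 * refl, v2 * refl), "mp", ri, -1)]
        return out


def make_family(spec: GeneratorSpec) -> list[LabelledBasis]:
    """Generate ``spec.n`` labelled bases from the requested family.

    For ``mirror_pairs`` the oblique family emits reflected pairs, so the
    output holds ``2 n`` bases with exactly balanced chirality.  The
    ``mixed`` family cycles uniformly at random through all five classes.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[LabelledBasis] = []
    for _ in range(spec.n):
        fam = spec.family
        if fam == "mixed":
            fam = str(rng.choice(FAMILIES[:5]))
        for lb in _one_sample(fam, rng, spec):
            basis = _scrambled(lb.basis, rng, spec.max_shears) if spec.scramble else lb.basis
            out.append(LabelledBasis(basis, lb.label, lb.ri_true, lb.sign_true))
    return out


# ---------------------------------------------------------------------------
# 3D cell tables
# ---------------------------------------------------------------------------

_CELL_FAMILIES = ("cubic", "orthorhombic", "hexagonal", "monoclinic", "triclinic")


def _draw_cell(family: str, rng: np.random.Generator,
               a_range: tuple[float, float]) -> tuple[float, ...]:
    lo, hi = a_range
    if family == "cubic":
        a = rng.uniform(lo, hi)
        return (a, a, a, 90.0, 90.0, 90.0)
    if family == "orthorhombic":
        a, b, c = sorted(rng.uniform(lo, hi, size=3))
        return (a, b * 1.01, c * 1.02, 90.0, 90.0, 90.0)
    if family == "hexagonal":
        a = rng.uniform(lo, hi)
        c = rng.uniform(lo, hi)
        return (a, a, c, 90.0, 90.0, 120.0)
    if family == "monoclinic":
        a, b, c = rng.uniform(lo, hi, size=3)
        beta = rng.uniform(95.0, 130.0)
        return (a, b, c, 90.0, beta, 90.0)
    if family == "triclinic":
        while True:
            a, b, c = rng.uniform(lo, hi, size=3)
            al, be, ga = rng.uniform(70.0, 110.0, size=3)
            if min(abs(al - 90), abs(be - 90), abs(ga - 90)) < 2.0:
                continue
            ca, cb, cg = (math.cos(math.radians(v)) for v in (al, be, ga))
            if 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg > 1e-4:
                return (a, b, c, al, be, ga)
    raise AssertionError(family)


def make_cell_table(
    n: int,
    seed: int,
    families: tuple[str, ...] = _CELL_FAMILIES,
    a_range: tuple[float, float] = (2.5, 25.0),
    cluster_fraction: float = 0.0,
    cluster_cell: tuple[float, float, float, float, float, float] = (3.5, 5.2, 11.9, 90.0, 103.0, 90.0),
    cluster_jitter: float = 0.005,
) -> pd.DataFrame:
    """Emulate a database extract: a table of valid 3D unit cells.

    A ``cluster_fraction`` of rows are drawn as tiny jitters around
    ``cluster_cell``, mimicking the hot spots that hundreds of
    re-determinations of the same well-studied structure produce in real
    parameter heat maps.  Deterministic for a fixed seed.
    """
    for fam in families:
        if fam not in _CELL_FAMILIES:
            raise LatticeError(f"unknown 3D cell family {fam!r}")
    rng = np.random.default_rng(seed)
    rows = []
    n_cluster = int(round(n * cluster_fraction))
    for i in range(n):
        if i < n_cluster:
            base = np.asarray(cluster_cell, dtype=float)
            jit = rng.normal(0.0, cluster_jitter, size=6)
            jit[3:] *= 0.1  # angles jitter less than lengths, as in refinements
            vals = tuple(base + jit)
        else:
            fam = families[int(rng.integers(0, len(families)))]
            vals = _draw_cell(fam, rng, a_range)
        Cell3D(*vals, id=f"syn{i:05d}")  # validation only
        rows.append((f"syn{i:05d}", *vals))
    return pd.DataFrame(rows, columns=["id", "a", "b", "c", "alpha", "beta", "gamma"])
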