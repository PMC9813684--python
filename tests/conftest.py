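"""Shared fixtures and independent oracles for the lat2d test suite.

The oracles here deliberately avoid the code paths they check:

* :func:`brute_force_conorms` finds the minimal-norm superbase by exhaustive
  search over bounded integer changes of basis (the obtuse superbase is the
  unique norm-sum minimiser, so this is an independent route to the conorms).
* :func:`lagrange_gauss_conorms` reduces the basis by the classical
  Lagrange-Gauss algorithm and reads the conorms off the shortest basis.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from lat2d import Basis2D
from lat2d.fixtures import random_unimodular

_UNIMODULAR_POOL: tuple[np.ndarray, ...] | None = None


def _unimodular_pool(bound: int = 10) -> tuple[np.ndarray, ...]:
    """All 2x2 integer matrices with entries in [-bound, bound] and det ±1,
    as flat coefficient arrays (a, b, c, d) for vectorised evaluation."""
    global _UNIMODULAR_POOL
    if _UNIMODULAR_POOL is None:
        r = np.arange(-bound, bound + 1)
        a, b, c, d = np.meshgrid(r, r, r, r, indexing="ij")
        a, b, c, d = (m.ravel() for m in (a, b, c, d))
        mask = np.abs(a * d - b * c) == 1
        _UNIMODULAR_POOL = (a[mask], b[mask], c[mask], d[mask])
    return _UNIMODULAR_POOL


def brute_force_conorms(basis: Basis2D, bound: int = 10) -> tuple[float, float, float]:
    """Sorted conorm triple of the minimal-norm superbase found by exhaustive
    search over unimodular re-basings with entries in [-bound, bound]."""
    a, b, c, d = _unimodular_pool(bound)
    v1, v2 = basis.v1, basis.v2
    # columns of B @ M for M = [[a, b], [c, d]]
    w1x, w1y = a * v1[0] + c * v2[0], a * v1[1] + c * v2[1]
    w2x, w2y = b * v1[0] + d * v2[0], b * v1[1] + d * v2[1]
    w0x, w0y = -w1x - w2x, -w1y - w2y
    ns = (w1x**2 + w1y**2) + (w2x**2 + w2y**2) + (w0x**2 + w0y**2)
    i = int(np.argmin(ns))
    p12 = -(w1x[i] * w2x[i] + w1y[i] * w2y[i])
    p01 = -(w0x[i] * w1x[i] + w0y[i] * w1y[i])
    p02 = -(w0x[i] * w2x[i] + w0y[i] * w2y[i])
    return tuple(sorted((float(p12), float(p01), float(p02))))


def lagrange_gauss_conorms(basis: Basis2D) -> tuple[float, float, float]:
    """Conorms via classical Lagrange-Gauss reduction of the basis."""
    v1, v2 = basis.v1.copy(), basis.v2.copy()
    if v1 @ v1 > v2 @ v2:
        v1, v2 = v2, v1
    while True:
        m = round(float(v1 @ v2) / float(v1 @ v1))
        v2 = v2 - m * v1
        if v2 @ v2 >= v1 @ v1:
            break
        v1, v2 = v2, v1
    if v1 @ v2 > 0:
        v2 = -v2
    v0 = -v1 - v2
    return tuple(sorted((float(-v1 @ v2), float(-v0 @ v1), float(-v0 @ v2))))


def random_oblique_basis(rng: np.random.Generator, max_shears: int = 3) -> Basis2D:
    """A generic scrambled basis whose reducing transform stays within the
    brute-force search bound (scrambling uses at most ``max_shears`` shears,
    so the inverse re-basing has entries at most 2**max_shears)."""
    a = rng.uniform(1.0, 3.0)
    b = a * rng.uniform(1.05, 2.0)
    gmax = math.degrees(math.acos(-a / (2.0 * b)))
    gamma = math.radians(rng.uniform(91.0, gmax - 1.0))
    v1 = np.array([a, 0.0])
    v2 = np.array([b * math.cos(gamma), b * math.sin(gamma)])
    m = random_unimodular(rng, int(rng.integers(0, max_shears + 1))).astype(float)
    theta = rng.uniform(0, 2 * math.pi)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    cols = rot @ (np.column_stack((v1, v2)) @ m)
    return Basis2D(cols[:, 0], cols[:, 1])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230101)
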