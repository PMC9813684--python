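"""Root/projected invariants, chirality sign and dissymmetry distances."""

import math

import numpy as np
from conftest import random_oblique_basis
from hypothesis import given, settings
from hypothesis import strategies as st

from lat2d import (
    Basis2D,
    ProjectedInvariant,
    RootInvariant,
    dissymmetry,
    lattice_sign,
    projected_invariant,
    quadratic_invariant,
    reduced_cell,
    ri_distance,
    root_invariant,
    selling_reduce,
    size,
)

SQRT2 = math.sqrt(2.0)
SQRT3 = math.sqrt(3.0)
INCENTRE = 1.0 - 1.0 / SQRT2


def ri_of(basis: Basis2D) -> RootInvariant:
    return root_invariant(selling_reduce(basis))


class TestRootInvariant:
    def test_unit_square(self):
        assert ri_of(Basis2D([1, 0], [0, 1])).as_tuple() == (0.0, 1.0, 1.0)

    def test_hexagonal(self):
        got = ri_of(Basis2D([1, 0], [-0.5, SQRT3 / 2]))
        np.testing.assert_allclose(got.as_tuple(), [1 / SQRT2] * 3, rtol=1e-12)

    def test_centred_rectangular_half_cell_1x2(self):
        # superbase (2a,0), (-a,b), (-a,-b) has conorms (2a^2, 2a^2, b^2-a^2)
        got = ri_of(Basis2D([2, 0], [-1, 2]))
        np.testing.assert_allclose(got.as_tuple(), (SQRT2, SQRT2, SQRT3), rtol=1e-12)

    def test_scale_equivariance(self, rng):
        for _ in range(20):
            basis = random_oblique_basis(rng)
            c = rng.uniform(0.1, 10.0)
            scaled = Basis2D(c * basis.v1, c * basis.v2)
            np.testing.assert_allclose(
                ri_of(scaled).as_tuple(), c * np.array(ri_of(basis).as_tuple()),
                rtol=1e-9)


class TestLatticeSign:
    def test_rectangular_lattices_achiral(self):
        for a, b in ((1, 1), (1, 3), (2.5, 7)):
            assert lattice_sign(selling_reduce(Basis2D([a, 0], [0, b]))) == 0

    def test_positively_oriented_oblique(self):
        # lengths 1.9 < 3.634 < 4.017 already ordered; det > 0
        assert lattice_sign(selling_reduce(Basis2D([1.9, 0], [-0.18, 3.63]))) == 1

    def test_reflection_flips_sign(self):
        assert lattice_sign(selling_reduce(Basis2D([1.9, 0], [-0.18, -3.63]))) == -1

    def test_reflection_fixes_ri_and_flips_sign_randomly(self, rng):
        for _ in range(100):
            basis = random_oblique_basis(rng)
            mirrored = Basis2D(basis.v1 * [1, -1], basis.v2 * [1, -1])
            sb, sbm = selling_reduce(basis), selling_reduce(mirrored)
            np.testing.assert_allclose(root_invariant(sb).as_tuple(),
                                       root_invariant(sbm).as_tuple(), rtol=1e-9)
            s = lattice_sign(sb)
            if s != 0:
                assert lattice_sign(sbm) == -s


class TestCompleteness:
    def test_oriented_invariant_fixed_by_rebasing_and_rotation(self, rng):
        """Complete-invariant surrogate: RI and sign never change under any
        change of basis or rotation of the same lattice (500 x 10)."""
        from lat2d.fixtures import random_unimodular

        for _ in range(500):
            basis = random_oblique_basis(rng)
            sb = selling_reduce(basis)
            ref_ri = np.array(root_invariant(sb).as_tuple())
            ref_sign = lattice_sign(sb)
            for _ in range(10):
                m = random_unimodular(rng, 3).astype(float)
                theta = rng.uniform(0, 2 * math.pi)
                rot = np.array([[math.cos(theta), -math.sin(theta)],
                                [math.sin(theta), math.cos(theta)]])
                cols = rot @ (np.column_stack((basis.v1, basis.v2)) @ m)
                sb2 = selling_reduce(Basis2D(cols[:, 0], cols[:, 1]))
                np.testing.assert_allclose(root_invariant(sb2).as_tuple(), ref_ri,
                                           rtol=1e-9)
                assert lattice_sign(sb2) == ref_sign


class TestSize:
    def test_examples(self):
        assert size(RootInvariant(0, 1, 1)) == 2.0
        np.testing.assert_allclose(size(RootInvariant(*[1 / SQRT2] * 3)), 3 / SQRT2)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(deadline=None, max_examples=50)
    def test_homogeneity(self, r, c):
        ri = RootInvariant(r / 2, r, 2 * r)
        scaled = RootInvariant(c * r / 2, c * r, 2 * c * r)
        assert math.isclose(size(scaled), c * size(ri), rel_tol=1e-12)


class TestProjectedInvariant:
    def test_hexagonal_maps_to_top_vertex(self):
        pi = projected_invariant(ri_of(Basis2D([1, 0], [-0.5, SQRT3 / 2])))
        np.testing.assert_allclose((pi.x, pi.y), (0, 1), atol=1e-12)

    def test_square_maps_to_origin(self):
        pi = projected_invariant(ri_of(Basis2D([1, 0], [0, 1])))
        assert (pi.x, pi.y) == (0.0, 0.0)

    def test_published_incentre_lattice_basis(self):
        # the inversely designed basis (1.9, 0), (-0.18, 3.63) lands within
        # 0.01 of the incentre (rounded input coordinates)
        pi = projected_invariant(ri_of(Basis2D([1.9, 0], [-0.18, 3.63])))
        assert abs(pi.x - INCENTRE) < 0.01
        assert abs(pi.y - INCENTRE) < 0.01

    def test_rectangular_1x3(self):
        pi = projected_invariant(ri_of(Basis2D([1, 0], [0, 3])))
        np.testing.assert_allclose((pi.x, pi.y), (0.5, 0.0), atol=1e-12)

    def test_scale_invariance(self, rng):
        basis = random_oblique_basis(rng)
        ri = ri_of(basis)
        for c in (0.01, 3.7, 250.0):
            ri_c = RootInvariant(c * ri.r12, c * ri.r01, c * ri.r02)
            a, b = projected_invariant(ri), projected_invariant(ri_c)
            np.testing.assert_allclose((a.x, a.y), (b.x, b.y), rtol=1e-12)

    def test_qt_containment_10000_random_lattices(self, rng):
        """Every valid lattice projects inside the quotient triangle, and the
        hypotenuse is attained exactly when r12 = r01."""
        for _ in range(10_000):
            basis = random_oblique_basis(rng)
            ri = ri_of(basis)
            pi = projected_invariant(ri)
            assert 0.0 <= pi.x < 1.0
            assert 0.0 <= pi.y <= 1.0
            assert pi.x + pi.y <= 1.0 + 1e-12
            on_hyp = pi.x + pi.y >= 1.0 - 1e-9
            assert on_hyp == (abs(ri.r12 - ri.r01) <= 1e-9 * size(ri))

    def test_lipschitz_spot_check(self, rng):
        """Perturbing every basis coordinate by eps <= 1e-4 moves RI by at
        most C * eps with a finite, stable empirical constant (away from
        the degenerate r12 -> 0 boundary where the square root is only
        Hoelder continuous)."""
        eps = 1e-4
        maxima = []
        for batch in range(2):
            worst = 0.0
            trials = 0
            while trials < 500:
                basis = random_oblique_basis(rng)
                ri = ri_of(basis)
                if ri.r12 / size(ri) < 0.02:
                    continue
                trials += 1
                delta = rng.uniform(-eps, eps, size=(2, 2))
                pert = Basis2D(basis.v1 + delta[0], basis.v2 + delta[1])
                worst = max(worst, ri_distance(ri, ri_of(pert)) / eps)
            maxima.append(worst)
        assert all(np.isfinite(m) for m in maxima)
        assert max(maxima) < 100.0
        # stability: the two independent batches agree in order of magnitude
        assert max(maxima) < 10.0 * max(min(maxima), 1e-12)

    def test_centred_rectangular_edge_switch_at_sqrt3(self):
        """Half-cell ratio b/a below sqrt(3): vertical edge x = 0; above:
        hypotenuse x + y = 1; exactly sqrt(3): the hexagonal vertex."""
        for ratio in (1.2, 1.6):
            pi = projected_invariant(ri_of(Basis2D([2, 0], [-1, ratio])))
            assert abs(pi.x) < 1e-12 and 0 < pi.y < 1
        for ratio in (1.9, 3.0):
            pi = projected_invariant(ri_of(Basis2D([2, 0], [-1, ratio])))
            assert abs(pi.x + pi.y - 1.0) < 1e-12 and 0 < pi.y < 1
        pi = projected_invariant(ri_of(Basis2D([2, 0], [-1, SQRT3])))
        np.testing.assert_allclose((pi.x, pi.y), (0, 1), atol=1e-12)


class TestQuadraticInvariant:
    def test_unit_square(self):
        rc = reduced_cell(selling_reduce(Basis2D([1, 0], [0, 1])))
        qi = quadratic_invariant(rc)
        assert (qi.tau11, qi.tau12, qi.tau22) == (1.0, 0.0, 1.0)

    def test_oblique_lattice_reduced_form(self):
        # the basis (3,0), (-1,2) carries the form 9x^2 - 6xy + 5y^2, but is
        # not reduced: the lattice's shortest vectors have lengths sqrt(5)
        # and sqrt(8), giving the reduced form 5x^2 - 4xy + 8y^2 and hence
        # QI = (sqrt(5), sqrt(2), sqrt(8))
        rc = reduced_cell(selling_reduce(Basis2D([3, 0], [-1, 2])))
        qi = quadratic_invariant(rc)
        np.testing.assert_allclose((qi.tau11, qi.tau12, qi.tau22),
                                   (math.sqrt(5.0), SQRT2, math.sqrt(8.0)),
                                   rtol=1e-12)
        # the same form arises from the mirrored basis: QI cannot see chirality
        rcm = reduced_cell(selling_reduce(Basis2D([3, 0], [-1, -2])))
        assert quadratic_invariant(rcm) == qi

    def test_hexagonal(self):
        rc = reduced_cell(selling_reduce(Basis2D([1, 0], [-0.5, SQRT3 / 2])))
        qi = quadratic_invariant(rc)
        np.testing.assert_allclose((qi.tau11, qi.tau12, qi.tau22),
                                   (1.0, 1 / SQRT2, 1.0), rtol=1e-12)


class TestRiDistance:
    def test_identity_and_componentwise(self):
        a = RootInvariant(0, 1, 1)
        assert ri_distance(a, a) == 0.0
        assert ri_distance(a, RootInvariant(0, 1, 2)) == 1.0

    def test_metric_axioms_on_random_pairs(self, rng):
        tri = lambda: RootInvariant(*np.sort(rng.uniform(0.1, 5, 3)))
        for _ in range(100):
            a, b, c = tri(), tri(), tri()
            assert ri_distance(a, b) == ri_distance(b, a) >= 0
            assert ri_distance(a, c) <= ri_distance(a, b) + ri_distance(b, c) + 1e-12


class TestDissymmetry:
    def test_square_lattice_has_zero_tp_distance(self):
        d = dissymmetry(projected_invariant(ri_of(Basis2D([1, 0], [0, 1]))))
        assert d["tp"] == 0.0

    def test_rectangular_point_against_planar_geometry_oracle(self):
        from shapely.geometry import LineString, Point

        pi = ProjectedInvariant(0.5, 0.0, 0)
        d = dissymmetry(pi)
        assert d["op"] == 0.0
        p = Point(0.5, 0.0)
        oc_oracle = min(p.distance(LineString([(0, 0), (0, 1)])),
                        p.distance(LineString([(1, 0), (0, 1)])))
        np.testing.assert_allclose(d["oc"], oc_oracle, rtol=1e-12)

    def test_interior_point_all_positive(self):
        d = dissymmetry(ProjectedInvariant(0.2, 0.3, 1))
        assert all(v > 0 for v in d.values())

    def test_matches_shapely_on_random_interior_points(self, rng):
        from shapely.geometry import LineString, Point

        segs = {"op": LineString([(0, 0), (1, 0)])}
        for _ in range(50):
            x = rng.uniform(0.01, 0.9)
            y = rng.uniform(0.01, 0.95 - x)
            d = dissymmetry(ProjectedInvariant(x, y, 1))
            p = Point(x, y)
            np.testing.assert_allclose(d["op"], p.distance(segs["op"]), rtol=1e-10)
            oc = min(p.distance(LineString([(0, 0), (0, 1)])),
                     p.distance(LineString([(1, 0), (0, 1)])))
            np.testing.assert_allclose(d["oc"], oc, rtol=1e-10)
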