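# Methods

This note records the model behind `lat2d`, the conventions and numerical
choices the implementation fixes, what the synthetic generators do and do
not emulate, and the known limitations.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Reduction model

A 2D lattice is represented by the conorms (p₁₂, p₀₁, p₀₂) of its obtuse
superbase v₀ + v₁ + v₂ = 0, p_ij = −v_i·v_j ≥ 0.  `selling_reduce` starts
from (−v₁−v₂, v₁, v₂) and, while any pair is acute (v_i·v_j > tol),
applies the repair v_i → −v_i, v_k → v_k + 2v_i (third index k, v_j
kept).  Each step is unimodular, preserves the zero sum, and decreases
|v₀|² + |v₁|² + |v₂|² by exactly 4 v_i·v_j, so termination is guaranteed;
the obtuse superbase is the norm-sum minimiser, which the tests confirm
against an exhaustive bounded search and against classical
Lagrange–Gauss reduction.

Numerical choices:

* **Acute tolerance** — absolute `1e-12 · max |v_i|²`, scale-aware so
  exact right angles (dot products that are zero up to roundoff) do not
  cycle the loop.
* **Step order** — pairs are scanned in the fixed order (1,2), (0,1),
  (0,2) and the first violation is repaired.  Any order terminates; a
  fixed order makes runs bit-reproducible.
* **Canonical labelling** — output vectors are ordered |v₁| ≤ |v₂| ≤ |v₀|
  (hence p₁₂ ≤ p₀₁ ≤ p₀₂); length ties are broken by the lexicographically
  smallest conorm triple, and any remaining tie is a genuine symmetry of
  the lattice, so the choice cannot affect invariants.
* **Iteration cap** — 10 000 steps, unreachable in exact arithmetic; it
  guards hypothetical floating-point pathologies and raises rather than
  looping.
* **Degenerate input** — collinear bases and impossible cell-parameter
  triples are rejected with `LatticeError`; nothing is repaired silently.
* **Rigid-motion representative** — a lattice up to rigid motion is
  represented as (reduced-cell parameters, sign) obtained from the
  canonical superbase, using the 1–1 correspondence between non-acute
  reduced bases and obtuse superbases rather than an explicit inequality
  list on basis coordinates.

## Invariants and coordinates

* **Root invariant** RI = (√p₁₂, √p₀₁, √p₀₂) sorted ascending, in Å.
* **Sign** — 0 when r₁₂ ≤ tol·σ, |r₀₁ − r₁₂| ≤ tol·σ or
  |r₀₂ − r₀₁| ≤ tol·σ (those equalities characterise mirror symmetry);
  otherwise the sign of det[v₁ v₂] for the two shortest superbase
  vectors.  The default symmetry tolerance is **relative 1e-9**: tight on
  purpose, because real near-rectangular cells should remain oblique
  unless a caller opts into snapping (`--sym-tol`).  The same default and
  reasoning apply to Bravais classification, where vertices take
  precedence over edges so corner ambiguities resolve deterministically.
* **Projection** to the quotient triangle: x = (r₀₂ − r₀₁)/σ,
  y = 3r₁₂/σ with σ = r₁₂ + r₀₁ + r₀₂.  This specific coordinate pair is
  fixed by four independent anchors that the tests enforce: square →
  (0,0); hexagonal → (0,1); rectangular a × b → ((b−a)/(a+b), 0); and
  the inversely designed incentre lattice with basis (1.9, 0),
  (−0.18, 3.63) → within 0.01 of (1−1/√2, 1−1/√2) (its published basis
  coordinates are rounded to 2 decimals, hence the 0.01 slack).  One can
  check from the formulas that 0 ≤ x < 1, 0 ≤ y, x + y ≤ 1 always hold,
  with y = 0 iff r₁₂ = 0, x = 0 iff r₀₁ = r₀₂, and x + y = 1 iff
  r₁₂ = r₀₁ — the boundary is exactly the mirror-symmetric locus.
* **Quadratic invariant** (τ₁₁, τ₁₂, τ₂₂) = (a, √(−q₁₂), b) from the
  non-acute reduced cell, where q₁₂ = a·b·cos γ ≤ 0.  The middle
  component uses √(−q₁₂) so all three entries carry length units; the
  triple is ordered with a ≤ b, the canonical reduced-cell order.
* **Inverse design** — `reconstruct_from_RI` places
  v₁ = (√(p₁₂+p₀₁), 0) and solves v₁·v₂ = −p₁₂ for v₂ with positive
  (sign ≥ 0) or negative (sign = −1) y-component.  The round trip
  through `selling_reduce` reproduces (RI, sign) to relative 1e-9 and is
  property-tested on random triples.
* **Distances** — `ri_distance` is the Chebyshev (L∞) metric on RI
  triples, a deliberate convenience choice; `dissymmetry` reports
  Euclidean QT distances to the four higher-symmetry strata.  Neither is
  a calibrated lattice metric; both vanish exactly on the right loci and
  satisfy the metric axioms, which is what the package needs.

## Spherical map

The incentre of the right isosceles triangle (0,0), (1,0), (0,1) is
(t, t) with t = 1 − 1/√2 (inradius (2−√2)/2).  Conventions, each pinned
by a printed worked value reproduced in the tests:

* **Greenwich point** G = (0, √2 − 1): the intersection of the line
  through (t, t) and the excluded vertex (1, 0) with the edge x = 0.
  Seen from the incentre, G lies at planar bearing
  atan2(√2−1−t, −t) = 157.5°.
* **Longitude** μ = wrap(bearing − 157.5°) into (−180°, 180°], where
  bearing is the planar atan2 angle of (x, y) seen from (t, t); for
  x = t exactly the bearing is sign(y−t)·90°.  Points on the open
  segment from (1, 0) to the incentre lie on the antimeridian and are
  assigned +180° exactly (detected by an exact collinearity test, not by
  the wrap, so floating-point cannot land them on −180°).  Anchors:
  square 67.5°, hexagonal −45°, hypotenuse midpoint −112.5°, the
  rectangular lattice below the incentre 112.5°, G itself 0°.
* **Latitude** φ = sign · 90° · (1 − s), where s is the fractional
  position of (x, y) along the ray from the incentre to its boundary
  hit (smallest positive ray-edge intersection).  Mirror-symmetric
  lattices (sign 0) lie on ∂QT and get φ = 0; the incentre is the pole
  of its hemisphere, where longitude is undefined
  (`SphereCoord.defined_longitude = False`).  An interior point with
  sign 0 is rejected as inconsistent rather than silently placed.
* **Greenwich ratio** — the centred rectangular family with half-cell
  a × b, b/a < √3 projects to the vertical edge with
  y = 3√(b²−a²)/(2a√2 + √(b²−a²)); solving y = √2 − 1 by bracketed
  root-finding (Brent, on the invariant pipeline itself) gives
  b/a ≈ 1.0979, i.e. 1.1 at two significant figures.
* All angles are handled in degrees end to end.

## Pipeline conventions

* A 3D cell contributes the three 2D lattices of its basis-vector pairs
  in the fixed order {v₂,v₃}, {v₁,v₃}, {v₁,v₂}; each pair (u, w) becomes
  the cell (|u|, |w|, ∠(u,w)) embedded right-handedly (first vector on
  +x, second with positive y).  Cell parameters cannot encode chirality,
  so this embedding convention is what fixes each sub-lattice's sign,
  deterministically; `map_bases` exists for callers whose bases carry
  meaningful orientation.
* Binning is half-open lower-inclusive ([k·p, (k+1)·p)); the top edge of
  each domain (y = 1 in QT, longitude 180°) folds into the last bin, so
  counts are conserved exactly — conservation is asserted at every stage.
  Out-of-domain points raise instead of being clipped, because they can
  only come from an upstream invariant violation.
* Heat-map CSV dumps are exact integer matrices with a one-line metadata
  header and round-trip bit-identically; PNG renderings (log scale:
  log₁₀(1+count)) are advisory.
* Row-level failures in table mapping are logged and skipped; a large
  heterogeneous table should not abort on one bad cell.
* Centred-rectangular parameter maps invert RI back to the half-cell via
  a = e/√2 and b = √(o² + a²), where e is the repeated component of the
  triple and o the remaining one (the two QT branches put the repeated
  pair in different positions).
* CIF ingestion is an optional gemmi-backed adapter producing the same
  cell table; the core pipeline consumes delimited text only.

## Synthetic generators

`fixtures.make_family` draws each Bravais family from its closed-form
superbase (e.g. centred rectangular from (2a, 0), (−a, b), (−a, −b),
conorms (b²−a², 2a², 2a²)), so every generated basis carries an exact
ground-truth RI, label and sign computed *independently of the reduction
under test*.  Default ranges a ∈ [1, 10] Å and b/a ∈ [1.1, 2.5] cover
the parameter scales typical of small-molecule crystals while keeping
families unambiguous; oblique sampling keeps a relative guard band of
1e-6 around the mirror-symmetric loci so ground-truth signs are well
defined, and `mirror_pairs` emits exactly balanced chiral pairs.

Scrambling (random rotation + unimodular re-basing, entries bounded via
a product of at most 4 elementary shears/swaps) changes the basis but
never the lattice.  It is **off by default**: a floating-point rotation
perturbs an exact-zero conorm into one of order machine-epsilon, whose
square root is ~1e-8 — visible when ground truth is compared at 1e-9.
Invariance under scrambling is therefore tested as its own property at
float-realistic tolerances, while ground-truth recovery uses exact
inputs.

`fixtures.make_cell_table` emulates a heterogeneous database extract:
cubic, orthorhombic, hexagonal, monoclinic and triclinic parameter draws
with a ∈ [2.5, 25] Å, plus an optional cluster mode that jitters many
rows around one fixed cell to mimic the hot spots produced by repeated
re-determinations of well-studied structures.  It does **not** attempt
to match the empirical parameter distribution, space-group frequencies
or correlations of any real database — so passing tests demonstrate the
correctness and invariance of the machinery on all lattice types and
near-degenerate cases, not statistical claims about real crystal
populations.  Each generator takes a single explicit seed and is
bit-reproducible.

## Problem sizes

Bulk suites run at sizes chosen to exercise the properties thoroughly on
a single CPU in seconds: 500 lattices × 10 re-basings for invariance,
200 bases against each reduction oracle (the exhaustive search spans all
~10⁵ unimodular matrices with entries ≤ 10), 10 000 lattices for
quotient-triangle containment and sphere-coordinate injectivity, 1000
random root invariants for reconstruction round trips, 5 × 1000 exact
lattices for Bravais ground-truth recovery, and a 1000-cell (3000
sub-lattice) table for end-to-end count conservation.

## Known limitations

* Everything is 2D: no Niggli reduction, no 3D root invariants.
* `ri_distance`/`dissymmetry` are convenience measures, not the
  calibrated metrics or chirality distances of the full theory.
* Root products are only Hölder-continuous (exponent ½) in the basis
  where a conorm vanishes, so the Lipschitz spot-check of RI is run away
  from that boundary; the mapped coordinates themselves remain continuous.
* Latitude/longitude are coordinates, not a geodesic metric; no
  area-true cartography is attempted.
* The CIF adapter reads cell parameters only (no symmetry expansion, no
  atom sites).
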