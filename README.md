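# lat2d — continuous classification and geographic maps of 2D lattices

`lat2d` classifies two-dimensional lattices **continuously**: instead of
snapping a lattice into one of the five discrete Bravais classes, it
computes complete, continuous isometry invariants that place every
lattice at a definite point of a moduli space — a quotient triangle, or
equivalently a sphere with geographic latitude/longitude coordinates.
This matters wherever lattices come from measured or simulated crystal
structures (crystallography, crystal-structure prediction, polymorph
screening): real cells are noisy, so two nearly identical lattices must
map to nearly identical descriptors, and near-symmetric lattices must be
recognisably *close to* a symmetry class rather than silently snapped
into it.

## The mathematics in brief

Every 2D lattice Λ has an **obtuse superbase**: vectors v₀, v₁, v₂ with
v₀ + v₁ + v₂ = 0 whose **conorms** p₁₂ = −v₁·v₂, p₀₁ = −v₀·v₁,
p₀₂ = −v₀·v₂ are all ≥ 0 (Selling/Delaunay reduction).  The obtuse
superbase is unique up to isometry, so the sorted **root invariant**

    RI(Λ) = (r₁₂, r₀₁, r₀₂),  r_ij = √p_ij   (ångströms)

is a *complete* isometry invariant: RI(Λ) = RI(Λ′) ⇔ Λ ≅ Λ′.  The
chirality **sign(Λ)** ∈ {−1, 0, +1} (0 exactly for mirror-symmetric
lattices) upgrades it to completeness up to rigid motion.  Dividing by
the **size** σ = r₁₂ + r₀₁ + r₀₂ removes scale and projects into the
quotient triangle QT with vertices (0,0), (1,0), (0,1):

    x = (r₀₂ − r₀₁)/σ,    y = 3 r₁₂/σ.

The Bravais classes are exactly the strata of QT: square lattices (tp)
at (0,0), hexagonal (hp) at (0,1), primitive rectangular (op) on the
open bottom edge, centred rectangular (oc) on the open vertical edge and
open hypotenuse, oblique (mp) in the interior.  Gluing the two chiral
copies of QT along the mirror-symmetric boundary gives a (punctured)
sphere: the incentre (t, t), t = 1 − 1/√2, becomes the north pole,
∂QT the equator, and each lattice receives a latitude φ ∈ [−90°, 90°]
(hemisphere = chirality) and longitude μ ∈ (−180°, 180°] measured from
the Greenwich meridian through G = (0, √2 − 1).

All of this is continuous under perturbations of the lattice — unlike
reduced bases, Niggli-style cell parameters or symmetry-group labels,
which can jump under arbitrarily small noise.

## Worked example

Classify the oblique lattice with basis v₁ = (1.9, 0), v₂ = (−0.18, 3.63):

```python
import numpy as np
from lat2d import (Basis2D, selling_reduce, root_invariant, lattice_sign,
                   projected_invariant, spherical_map, bravais_class, reduced_cell)

basis = Basis2D([1.9, 0.0], [-0.18, 3.63])
sb = selling_reduce(basis)
ri = root_invariant(sb)
sign = lattice_sign(sb)
pi = projected_invariant(ri, sign)
coord = spherical_map(pi)
rc = reduced_cell(sb)
print(f"conorms   p12={sb.p12:.4f}  p01={sb.p01:.4f}  p02={sb.p02:.4f}")
print(f"RI        ({ri.r12:.4f}, {ri.r01:.4f}, {ri.r02:.4f})   sign={sign:+d}")
print(f"reduced   a={rc.a:.4f} A  b={rc.b:.4f} A  gamma={rc.gamma:.2f} deg")
print(f"PI        (x, y) = ({pi.x:.4f}, {pi.y:.4f})   bravais={bravais_class(pi).label}")
print(f"sphere    latitude={coord.latitude:.2f}  longitude={coord.longitude:.2f}")
```

prints

```
conorms   p12=0.3420  p01=3.2680  p02=12.8673
RI        (0.5848, 1.8078, 3.5871)   sign=+1
reduced   a=1.9000 A  b=3.6345 A  gamma=92.84 deg
PI        (x, y) = (0.2976, 0.2934)   bravais=mp
sphere    latitude=88.88  longitude=-151.33
```

Reading: the obtuse superbase of this lattice has strictly positive
conorms, so the lattice is oblique (`mp`) and chiral (`sign=+1`).  Its
projected invariant (0.2976, 0.2934) sits almost exactly at the
incentre (t, t) ≈ (0.2929, 0.2929) of the quotient triangle — this is
the "most oblique" lattice, maximally far from every mirror-symmetric
class, and accordingly its latitude 88.88° is nearly the north pole.
A reflection of the basis would flip the latitude to −88.88° and keep
the longitude.

The same analysis runs from the shell on whole tables of 2D or 3D cells
(a 3D cell `id,a,b,c,alpha,beta,gamma` contributes the three 2D lattices
spanned by its basis-vector pairs):

```bash
lat2d fixtures --family cells3d --n 1000 --seed 42 --out cells.csv
lat2d invariants --cells cells.csv --out invariants.tsv
lat2d map --cells cells.csv --space qt --pixel 0.005 --out qtmap
```

which writes per-lattice invariant records, an exact heat-map count
matrix (`qtmap_counts.csv`), an advisory rendering (`qtmap.png`) and a
count report by chirality and hemisphere (`qtmap_report.txt`).

## Layout

| module | contents |
| --- | --- |
| `lat2d.lattice_core` | bases, cells, Selling reduction, reduced cells, inverse design |
| `lat2d.invariants` | root/projected/quadratic invariants, sign, size, dissymmetry |
| `lat2d.sphere_map` | latitude/longitude, Greenwich conventions, boundary rays |
| `lat2d.bravais` | continuous-tolerance Bravais classification |
| `lat2d.pipeline` | cell tables → records → heat maps → reports |
| `lat2d.fixtures` | seeded synthetic generators with closed-form ground truth |
| `lat2d.cli` | the `lat2d` command |

Out of scope by design: 3D lattice invariants, Voronoi-domain metrics,
the calibrated metrics/chirality distances of the companion theory, and
database connectivity.
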