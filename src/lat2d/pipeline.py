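"""Mapping workflow: 3D cell tables -> invariants -> heat maps and reports.

Every 3D unit cell contributes three 2D lattices, generated by the basis
pairs {v2, v3}, {v1, v3}, {v1, v2} in that fixed order.  Each 2D lattice
is embedded with its first vector on the +x axis and a positive-y second
vector, Selling-reduced, and summarised by its root invariant, chirality
sign, projected invariant, Bravais class and sphere coordinates.  The
records then feed quotient-triangle and spherical heat maps, Bravais
parameter maps, and caption-style count reports.

Binning is half-open, lower-inclusive; the top edge of each domain is
folded into the last bin so boundary points (hexagonal lattices at
y = 1, longitude exactly 180°) are never lost.  All CSV outputs are
exact integer count matrices — images are advisory renderings only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bravais import bravais_class
from .invariants import (
    lattice_sign,
    projected_invariant,
    root_invariant,
    size,
)
from .lattice_core import Basis2D, Cell2D, Cell3D, LatticeError, basis3d_from_cell, cell_to_basis, selling_reduce
from .sphere_map import SphereCoord, spherical_map

logger = logging.getLogger("lat2d")

__all__ = [
    "HeatGrid",
    "extract_2d_lattices",
    "read_cell_table",
    "map_table",
    "bin_qt",
    "bin_sphere",
    "render",
    "parameter_maps",
    "figure_report",
    "cells_from_cif_dir",
]

SUBLATTICES = ("v2v3", "v1v3", "v1v2")

RECORD_COLUMNS = ["id", "sublattice", "r12", "r01", "r02", "sign", "sigma",
                  "x", "y", "bravais", "lat", "lon"]


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def extract_2d_lattices(cell: Cell3D) -> list[Cell2D]:
    """The three 2D lattices of a 3D cell, in the fixed pair order
    {v2, v3}, {v1, v3}, {v1, v2}.

    Each pair (u, w) becomes the 2D cell (|u|, |w|, angle(u, w)); the
    downstream right-handed planar embedding then fixes each sub-lattice's
    chirality deterministically.
    """
    v1, v2, v3 = basis3d_from_cell(cell)
    cells = []
    for u, w in ((v2, v3), (v1, v3), (v1, v2)):
        lu, lw = float(np.linalg.norm(u)), float(np.linalg.norm(w))
        cosang = float(u @ w) / (lu * lw)
        cosang = min(1.0, max(-1.0, cosang))
        cells.append(Cell2D(lu, lw, math.degrees(math.acos(cosang))))
    return cells


def read_cell_table(source: str | Path | pd.DataFrame, sep: str | None = None) -> pd.DataFrame:
    """Load a delimited-text table of cells (2D or 3D) into a DataFrame.

    Accepts columns ``id,a,b,gamma`` or ``id,a,b,c,alpha,beta,gamma``;
    the separator is sniffed (comma/tab/whitespace) unless given.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if set(cols) >= {"id", "a", "b", "c", "alpha", "beta", "gamma"}:
        pass
    elif set(cols) >= {"id", "a", "b", "gamma"}:
        pass
    else:
        raise LatticeError(f"unrecognised cell-table columns: {cols}")
    if df["id"].duplicated().any():
        raise LatticeError("cell-table ids must be unique")
    return df


def cells_from_cif_dir(path: str | Path) -> pd.DataFrame:
    """Optional CIF adapter: collect unit-cell parameters from ``*.cif`` files.

    Requires :mod:`gemmi`; the core pipeline itself only consumes
    delimited text.
    """
    import gemmi

    rows = []
    for f in sorted(Path(path).glob("*.cif")):
        doc = gemmi.cif.read(str(f))
        block = doc.sole_block()
        vals = [block.find_value(f"_cell_{k}")
                for k in ("length_a", "length_b", "length_c",
                          "angle_alpha", "angle_beta", "angle_gamma")]
        if any(v is None for v in vals):
            logger.warning("skipping %s: incomplete cell data", f.name)
            continue
        rows.append((f.stem, *(float(gemmi.cif.as_number(v)) for v in vals)))
    return pd.DataFrame(rows, columns=["id", "a", "b", "c", "alpha", "beta", "gamma"])


# ---------------------------------------------------------------------------
# invariant records
# ---------------------------------------------------------------------------

def _record_for_basis(row_id: str, sub: str, basis: Basis2D,
                      sym_tol: float, bravais_tol: float) -> dict:
    sb = selling_reduce(basis)
    ri = root_invariant(sb)
    sign = lattice_sign(sb, tol=sym_tol)
    pi = projected_invariant(ri, sign)
    coord: SphereCoord = spherical_map(pi)
    return {
        "id": row_id,
        "sublattice": sub,
        "r12": ri.r12, "r01": ri.r01, "r02": ri.r02,
        "sign": sign,
        "sigma": size(ri),
        "x": pi.x, "y": pi.y,
        "bravais": bravais_class(pi, tol=bravais_tol).label,
        "lat": coord.latitude,
        "lon": coord.longitude if coord.defined_longitude else float("nan"),
    }


def map_table(table: pd.DataFrame, sym_tol: float = 1e-9,
              bravais_tol: float = 1e-9) -> pd.DataFrame:
    """Per-lattice invariant records for every cell in the table.

    3D cells contribute three records (one per sub-lattice); 2D cells one.
    Invalid rows are logged and skipped; the run continues.  Output order
    follows the input order, so identical inputs give identical outputs.
    """
    table = read_cell_table(table)
    is3d = "c" in table.columns
    records = []
    for row in table.itertuples(index=False):
        try:
            if is3d:
                cell = Cell3D(row.a, row.b, row.c, row.alpha, row.beta, row.gamma,
                              id=str(row.id))
                for sub, c2 in zip(SUBLATTICES, extract_2d_lattices(cell)):
                    records.append(_record_for_basis(str(row.id), sub,
                                                     cell_to_basis(c2),
                                                     sym_tol, bravais_tol))
            else:
                c2 = Cell2D(row.a, row.b, row.gamma)
                records.append(_record_for_basis(str(row.id), "v1v2",
                                                 cell_to_basis(c2),
                                                 sym_tol, bravais_tol))
        except (LatticeError, ValueError) as exc:
            logger.warning("skipping row %s: %s", row.id, exc)
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def map_bases(bases: Iterable[Basis2D], ids: Sequence[str] | None = None,
              sym_tol: float = 1e-9, bravais_tol: float = 1e-9) -> pd.DataFrame:
    """Invariant records for explicit 2D bases (one record each).

    Unlike cell-parameter tables, explicit bases carry chirality, so this
    is the entry point when signed statistics matter.
    """
    records = []
    for i, basis in enumerate(bases):
        row_id = ids[i] if ids is not None else f"basis{i:05d}"
        records.append(_record_for_basis(row_id, "v1v2", basis, sym_tol, bravais_tol))
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# heat grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeatGrid:
    """Integer count matrix over a regular grid.

    ``counts[i, j]`` counts points with x in [x0 + j*px, x0 + (j+1)*px)
    and y in [y0 + i*py, y0 + (i+1)*py) — half-open, lower-inclusive,
    with the top edge of the domain folded into the last bin.
    """

    domain: str                 # 'QT', 'QS', 'sphere' or 'parameter-plane'
    pixel: tuple[float, float]  # (px, py)
    counts: np.ndarray          # shape (ny, nx), dtype int64
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or (counts < 0).any():
            raise ValueError("counts must be a non-negative 2D integer matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        """Exact serialisation: metadata header plus the raw count matrix."""
        with open(path, "w") as fh:
            fh.write(f"# domain={self.domain} px={self.pixel[0]!r} py={self.pixel[1]!r} "
                     f"x0={self.x0!r} y0={self.y0!r}\n")
            np.savetxt(fh, self.counts, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeatGrid":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(item.split("=", 1) for item in header)
            counts = np.loadtxt(fh, dtype=np.int64, delimiter=",", ndmin=2)
        return cls(domain=meta["domain"],
                   pixel=(float(meta["px"]), float(meta["py"])),
                   counts=counts, x0=float(meta["x0"]), y0=float(meta["y0"]))


def _bin_indices(values: np.ndarray, origin: float, pixel: float, nbins: int,
                 what: str) -> np.ndarray:
    idx = np.floor((values - origin) / pixel).astype(np.int64)
    top = idx == nbins  # exact upper-edge points fold into the last bin
    idx[top & np.isclose(values, origin + nbins * pixel)] = nbins - 1
    if (idx < 0).any() or (idx >= nbins).any():
        raise LatticeError(f"{what} values outside the grid domain")
    return idx


def bin_qt(points: np.ndarray | Sequence[tuple[float, float]],
           pixel: float = 0.005) -> HeatGrid:
    """Count projected invariants into square pixels of the quotient triangle.

    Out-of-domain points (x not in [0, 1), y not in [0, 1] or x + y > 1)
    raise an error: they indicate an upstream invariant violation.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    nb = int(round(1.0 / pixel))
    eps = 1e-9
    if len(pts):
        x, y = pts[:, 0], pts[:, 1]
        if ((x < -eps) | (x >= 1.0) | (y < -eps) | (y > 1.0 + eps)
                | (x + y > 1.0 + eps)).any():
            raise LatticeError("points outside the quotient triangle")
    counts = np.zeros((nb, nb), dtype=np.int64)
    if len(pts):
        ix = _bin_indices(pts[:, 0], 0.0, pixel, nb, "QT x")
        iy = _bin_indices(np.minimum(pts[:, 1], 1.0), 0.0, pixel, nb, "QT y")
        np.add.at(counts, (iy, ix), 1)
    return HeatGrid(domain="QT", pixel=(pixel, pixel), counts=counts)


def bin_qs(points_with_sign: np.ndarray, pixel: float = 0.005) -> HeatGrid:
    """Count oriented projected invariants into the quotient square QS.

    QS glues two copies of QT along the hypotenuse: positive-sign (and
    mirror-symmetric) lattices keep their QT coordinates, negative-sign
    lattices are reflected to (1 - y, 1 - x) on the other half of the
    unit square.  Input rows are (x, y, sign).
    """
    arr = np.asarray(points_with_sign, dtype=float).reshape(-1, 3)
    pts = arr[:, :2].copy()
    neg = arr[:, 2] < 0
    pts[neg] = np.column_stack((1.0 - pts[neg, 1], 1.0 - pts[neg, 0]))
    nb = int(round(1.0 / pixel))
    counts = np.zeros((nb, nb), dtype=np.int64)
    if len(pts):
        if ((pts < -1e-9) | (pts > 1.0 + 1e-9)).any():
            raise LatticeError("points outside the quotient square")
        ix = _bin_indices(np.minimum(pts[:, 0], 1.0), 0.0, pixel, nb, "QS x")
        iy = _bin_indices(np.minimum(pts[:, 1], 1.0), 0.0, pixel, nb, "QS y")
        np.add.at(counts, (iy, ix), 1)
    return HeatGrid(domain="QS", pixel=(pixel, pixel), counts=counts)


def bin_sphere(coords: Iterable[SphereCoord] | np.ndarray,
               pixel: float = 1.0) -> HeatGrid:
    """Count sphere coordinates into a latitude-longitude grid.

    Rows are latitude bins over [-90, 90], columns longitude bins over
    (-180, 180].  Pole points (undefined longitude) land in the first
    longitude column of their polar cap row; with 1° pixels the caps are
    the rows |φ| ∈ [89, 90].
    """
    rows = []
    for c in coords:
        if isinstance(c, SphereCoord):
            rows.append((c.latitude, c.longitude if c.defined_longitude else -180.0 + pixel / 2))
        else:
            rows.append((float(c[0]), float(c[1])))
    arr = np.asarray(rows, dtype=float).reshape(-1, 2)
    nlat = int(round(180.0 / pixel))
    nlon = int(round(360.0 / pixel))
    counts = np.zeros((nlat, nlon), dtype=np.int64)
    if len(arr):
        lat, lon = arr[:, 0], arr[:, 1]
        if ((lat < -90.0) | (lat > 90.0) | (lon <= -180.0 - 1e-9) | (lon > 180.0)).any():
            raise LatticeError("coordinates outside the sphere domain")
        ilat = _bin_indices(lat, -90.0, pixel, nlat, "latitude")
        ilon = _bin_indices(lon, -180.0, pixel, nlon, "longitude")
        np.add.at(counts, (ilat, ilon), 1)
    return HeatGrid(domain="sphere", pixel=(pixel, pixel), counts=counts,
                    x0=-180.0, y0=-90.0)


def render(grid: HeatGrid, scale: str = "log",
           out_prefix: str | Path | None = None):
    """Render a heat grid to an image and dump the exact counts as CSV.

    ``scale='log'`` colours pixels by log10(1 + count); ``'linear'`` by
    the raw count.  The CSV is the bit-exact interface; the PNG is an
    advisory visualisation.  Returns the matplotlib figure (and writes
    ``<prefix>_counts.csv`` / ``<prefix>.png`` when a prefix is given).
    """
    import matplotlib.pyplot as plt

    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    if grid.total == 0:
        logger.warning("rendering an empty heat grid")
    img = np.log10(1.0 + grid.counts) if scale == "log" else grid.counts.astype(float)
    ny, nx = grid.counts.shape
    extent = (grid.x0, grid.x0 + nx * grid.pixel[0],
              grid.y0, grid.y0 + ny * grid.pixel[1])
    fig, ax = plt.subplots(figsize=(6, 6 * ny * grid.pixel[1] / (nx * grid.pixel[0])))
    ax.imshow(img, origin="lower", extent=extent, aspect="auto", cmap="hot_r")
    ax.set_title(f"{grid.domain} heat map ({scale} scale, n={grid.total})")
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        grid.to_csv(out_prefix.with_name(out_prefix.name + "_counts.csv"))
        fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Bravais-class parameter maps and caption-style reports
# ---------------------------------------------------------------------------

def _oc_half_cell(r12: float, r01: float, r02: float) -> tuple[float, float]:
    """Invert the centred-rectangular root invariant to half-cell sides (a, b).

    Two of the three components equal a√2; the remaining one is
    √(b² - a²) — which of the two patterns occurs depends on whether
    b/a is below or above √3 (vertical edge vs hypotenuse of QT).
    """
    if abs(r01 - r02) <= abs(r01 - r12):
        equal, other = r01, r12
    else:
        equal, other = r01, r02
    a = equal / math.sqrt(2.0)
    return a, math.sqrt(other * other + a * a)


def parameter_maps(records: pd.DataFrame, pixel: float = 0.1,
                   hist_bin: float = 0.1) -> dict:
    """Per-class parameter summaries, as in database-scale survey figures.

    Rectangular (op) lattices are mapped by their primitive cell sides
    (a, b) = (r01, r02); centred rectangular (oc) by the conventional
    half-cell sides recovered from the root invariant; square (tp) and
    hexagonal (hp) by histograms of the minimum inter-point distance
    (a = r01 for tp, a = r12·√2 for hp).
    """
    out: dict = {}
    op = records[records["bravais"] == "op"]
    oc = records[records["bravais"] == "oc"]
    tp = records[records["bravais"] == "tp"]
    hp = records[records["bravais"] == "hp"]

    def _grid(a: np.ndarray, b: np.ndarray) -> HeatGrid:
        if len(a) == 0:
            return HeatGrid("parameter-plane", (pixel, pixel),
                            np.zeros((1, 1), dtype=np.int64))
        x0 = math.floor(a.min() / pixel) * pixel
        y0 = math.floor(b.min() / pixel) * pixel
        nx = int(math.floor((a.max() - x0) / pixel)) + 1
        ny = int(math.floor((b.max() - y0) / pixel)) + 1
        counts = np.zeros((ny, nx), dtype=np.int64)
        ix = np.floor((a - x0) / pixel).astype(np.int64).clip(0, nx - 1)
        iy = np.floor((b - y0) / pixel).astype(np.int64).clip(0, ny - 1)
        np.add.at(counts, (iy, ix), 1)
        return HeatGrid("parameter-plane", (pixel, pixel), counts, x0=x0, y0=y0)

    out["op"] = _grid(op["r01"].to_numpy(), op["r02"].to_numpy())
    if len(oc):
        ab = np.array([_oc_half_cell(r.r12, r.r01, r.r02)
                       for r in oc.itertuples(index=False)])
        out["oc"] = _grid(ab[:, 0], ab[:, 1])
    else:
        out["oc"] = _grid(np.array([]), np.array([]))

    def _hist(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if len(a) == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(1)
        lo = math.floor(a.min() / hist_bin) * hist_bin
        hi = math.floor(a.max() / hist_bin) * hist_bin + hist_bin
        edges = np.arange(lo, hi + hist_bin / 2, hist_bin)
        counts, edges = np.histogram(a, bins=edges)
        return counts.astype(np.int64), edges

    out["tp"] = _hist(tp["r01"].to_numpy())
    out["hp"] = _hist(hp["r12"].to_numpy() * math.sqrt(2.0))
    return out


def figure_report(records: pd.DataFrame) -> str:
    """Caption-style count summary over the standard sign/hemisphere filters.

    Mirrors the taxonomy of database-survey figure captions (counts for
    sign >= 0, sign > 0, sign <= 0, sign < 0, eastern/western longitude
    hemispheres, and oblique-only variants) so synthetic runs can be read
    side by side with published maps.
    """
    n = len(records)
    sign = records["sign"]
    lon = records["lon"]
    oblique = sign != 0
    lines = [
        f"records: {n}",
        f"sign > 0: {int((sign > 0).sum())}",
        f"sign = 0: {int((sign == 0).sum())}",
        f"sign < 0: {int((sign < 0).sum())}",
        f"sign >= 0: {int((sign >= 0).sum())}",
        f"sign <= 0: {int((sign <= 0).sum())}",
        f"longitude in (-180, 0]: {int(((lon > -180) & (lon <= 0)).sum())}",
        f"longitude in [0, 180): {int(((lon >= 0) & (lon < 180)).sum())}",
        f"longitude undefined (poles): {int(lon.isna().sum())}",
        f"oblique (sign != 0): {int(oblique.sum())}",
        f"oblique, longitude in (-180, 0]: {int((oblique & (lon > -180) & (lon <= 0)).sum())}",
        f"oblique, longitude in [0, 180): {int((oblique & (lon >= 0) & (lon < 180)).sum())}",
    ]
    counts = records["bravais"].value_counts()
    for label in ("tp", "hp", "op", "oc", "mp"):
        if label in counts.index:
            lines.append(f"bravais {label}: {int(counts[label])}")
    return "\n".join(lines) + "\n"
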