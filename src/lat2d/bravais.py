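"""Bravais classification of 2D lattices from quotient-triangle coordinates.

The five 2D Bravais classes partition the quotient triangle QT:

=====  =======================================  ==========================
label  lattices                                 locus in QT
=====  =======================================  ==========================
tp     square (tetragonal)                      vertex (0, 0)
hp     hexagonal                                vertex (0, 1)
op     primitive rectangular                    open edge y = 0
oc     centred rectangular                      open edge x = 0 and open
                                                hypotenuse x + y = 1
mp     oblique (generic)                        interior
=====  =======================================  ==========================

Classification is a nearest-subspace test with an explicit tolerance in
QT Euclidean distance, with vertices taking precedence over edges so a
point within tolerance of (0, 0) is labelled tp even though it is also
near two edges.  The default tolerance is tight (1e-9): near-rectangular
experimental lattices stay oblique unless the caller opts in to snapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .invariants import ProjectedInvariant, _dist_point_segment

__all__ = ["BravaisLabel", "bravais_class", "class_counts", "LABELS"]

LABELS = ("tp", "hp", "op", "oc", "mp")

#: Default snapping tolerance (QT Euclidean distance) for class assignment.
DEFAULT_TOL = 1e-9


@dataclass(frozen=True)
class BravaisLabel:
    """An assigned Bravais class together with the tolerance used."""

    label: str
    tol: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown Bravais label {self.label!r}")


def bravais_class(pi: ProjectedInvariant, tol: float = DEFAULT_TOL) -> BravaisLabel:
    """Assign one of the five 2D Bravais classes to a projected invariant.

    Precedence is vertices > edges > interior, which resolves corner
    ambiguities deterministically: the square and hexagonal vertices win
    over the edges that meet there.
    """
    x, y = pi.x, pi.y
    if math.hypot(x, y) <= tol:
        label = "tp"
    elif math.hypot(x, y - 1.0) <= tol:
        label = "hp"
    elif _dist_point_segment((x, y), (0.0, 0.0), (1.0, 0.0)) <= tol:
        label = "op"
    elif min(_dist_point_segment((x, y), (0.0, 0.0), (0.0, 1.0)),
             _dist_point_segment((x, y), (1.0, 0.0), (0.0, 1.0))) <= tol:
        label = "oc"
    else:
        label = "mp"
    return BravaisLabel(label=label, tol=tol)


def class_counts(labels: Iterable[str | BravaisLabel]) -> pd.DataFrame:
    """Tally Bravais labels into a count/fraction table.

    Returns a DataFrame indexed by label with columns ``count`` and
    ``fraction``; labels absent from the input are omitted, and an empty
    input yields an empty table.
    """
    names = [lb.label if isinstance(lb, BravaisLabel) else str(lb) for lb in labels]
    if not names:
        return pd.DataFrame(columns=["count", "fraction"])
    counts = pd.Series(names).value_counts()
    counts = counts.reindex([lb for lb in LABELS if lb in counts.index])
    out = pd.DataFrame({"count": counts})
    out["fraction"] = out["count"] / out["count"].sum()
    out.index.name = "bravais"
    return out
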