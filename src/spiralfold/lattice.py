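"""Integer geometry of the 3D face-centred-cubic (FCC) lattice.

The FCC lattice is realised as the even-coordinate-sum sublattice of the
integer grid: every point ``(x, y, z)`` with ``x + y + z`` even.  Each point
has exactly 12 topological neighbours, reached by the 12 basis vectors of
squared Euclidean norm 2.  All chain geometry in this package lives on this
sublattice (chains are anchored at the origin, and every basis vector has
even coordinate sum, so the invariant propagates along the chain).

Points are plain ``(x, y, z)`` integer tuples: hashable, cheap, and exact.
Fractional reference points (the hydrophobic-core centre) are float triples.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Tuple

Point = Tuple[int, int, int]
FractionalPoint = Tuple[float, float, float]

#: The 12 FCC basis vectors, in a fixed published order.  The set is closed
#: under negation (6 antipodal pairs) and every vector has squared norm 2.
BASIS_VECTORS: Tuple[Point, ...] = (
    (1, 1, 0), (-1, -1, 0), (-1, 1, 0), (1, -1, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (0, -1, 1), (-1, 0, 1), (0, -1, -1), (-1, 0, -1),
)

_BASIS_SET = frozenset(BASIS_VECTORS)


def is_lattice_point(p: Sequence[int]) -> bool:
    """True iff ``p`` lies on the even-sum FCC sublattice."""
    return (p[0] + p[1] + p[2]) % 2 == 0


def is_adjacent(p: Point, q: Point) -> bool:
    """True iff ``q - p`` is one of the 12 basis vectors.

    Adjacency is symmetric because the basis-vector set is closed under
    negation.
    """
    return (q[0] - p[0], q[1] - p[1], q[2] - p[2]) in _BASIS_SET


def neighbours(p: Point) -> list[Point]:
    """The 12 topological neighbours of ``p``, in basis-vector order."""
    x, y, z = p
    return [(x + dx, y + dy, z + dz) for dx, dy, dz in BASIS_VECTORS]


def common_neighbours(p: Point, q: Point) -> list[Point]:
    """Lattice points adjacent to both ``p`` and ``q``, sorted
    lexicographically.

    The count depends on the relative placement of ``p`` and ``q``: two
    chain neighbours of a corner residue have up to 4 common neighbours
    (exactly 4 in the collinear distance-2 configuration), some geometries
    yield 2, and distant pairs share none.

    Raises
    ------
    ValueError
        If ``p == q`` (degenerate query).
    """
    if tuple(p) == tuple(q):
        raise ValueError("common_neighbours is undefined for p == q")
    qx, qy, qz = q
    out = [
        r for r in neighbours(p)
        if (qx - r[0], qy - r[1], qz - r[2]) in _BASIS_SET
    ]
    out.sort()
    return out


def distance(p: Sequence[float], c: Sequence[float]) -> float:
    """Euclidean distance between a (possibly fractional) pair of points."""
    return math.sqrt(
        (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2 + (p[2] - c[2]) ** 2
    )


def translate(p: Point, v: Sequence[int]) -> Point:
    """``p + v`` componentwise."""
    return (p[0] + v[0], p[1] + v[1], p[2] + v[2])


def centroid(points: Iterable[Sequence[float]]) -> FractionalPoint:
    """Arithmetic mean of a non-empty collection of points."""
    pts = list(points)
    if not pts:
        raise ValueError("centroid of an empty point collection")
    n = len(pts)
    return (
        sum(p[0] for p in pts) / n,
        sum(p[1] for p in pts) / n,
        sum(p[2] for p in pts) / n,
    )
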