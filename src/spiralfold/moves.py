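"""Move operators: the diagonal (corner-flip) move and the pull move.

The diagonal move relocates an interior residue ``i`` to a free common
neighbour of its two chain neighbours, leaving every other residue in
place; it is the only operator the spiral search itself uses.

The pull move is the classic local, reversible chain move used here by the
stagnation-recovery random walk.  Generalised to the FCC lattice: a target
point ``L`` (free neighbour of residue ``i+1`` when pulling the head side)
receives residue ``i``; an intermediate point ``C`` — a common neighbour of
``L`` and the old position of ``i`` — receives residue ``i-1`` unless ``C``
already *is* residue ``i-1``'s position, in which case the move degenerates
to a corner-flip; residues further down the pulled side then take the old
position of the residue two ahead of them until chain adjacency is
restored.  Pulling toward the tail mirrors this.  Successful pull moves
never produce an infeasible conformation, and every applied move has an
explicit inverse that restores the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Tuple

from .conformation import Conformation, ConformationError
from .lattice import Point, common_neighbours, is_adjacent, neighbours

__all__ = [
    "DiagonalMove",
    "PullMove",
    "diagonal_candidates",
    "apply_diagonal",
    "pull_candidates",
    "apply_pull",
    "inverse_pull",
]

Direction = Literal["toward_head", "toward_tail"]


@dataclass(frozen=True)
class DiagonalMove:
    """Corner-flip of residue ``residue`` to ``target``."""

    residue: int
    target: Point


@dataclass(frozen=True)
class PullMove:
    """A pull move as an explicit, validated displacement set.

    ``displacements`` lists ``(residue index, new point)`` pairs covering a
    contiguous index interval (the ``affected_range``).  Representing the
    move by its full displacement set makes the inverse trivial: swap each
    new point for the residue's pre-move point.
    """

    residue: int
    direction: Direction
    displacements: Tuple[Tuple[int, Point], ...]

    @property
    def target(self) -> Point:
        """The point the anchor residue moves to."""
        for i, p in self.displacements:
            if i == self.residue:
                return p
        raise ValueError("malformed pull move: anchor not displaced")

    @property
    def affected_range(self) -> Tuple[int, int]:
        """Inclusive (lo, hi) interval of displaced residues."""
        idx = [i for i, _ in self.displacements]
        return (min(idx), max(idx))


def diagonal_candidates(conf: Conformation, i: int) -> List[Point]:
    """Free common neighbours of residues ``i-1`` and ``i+1``.

    Lexicographically ordered.  Undefined (raises) at the chain termini,
    which lack one of the two flanking residues.
    """
    if not 0 < i < len(conf) - 1:
        raise ConformationError(
            f"diagonal move undefined for end residue {i}"
        )
    occ = conf.occupancy
    return [
        p
        for p in common_neighbours(conf.coords[i - 1], conf.coords[i + 1])
        if p not in occ
    ]


def apply_diagonal(conf: Conformation, move: DiagonalMove) -> Conformation:
    """Apply a diagonal move in place and return the conformation.

    Raises ConformationError (leaving ``conf`` unchanged) if the target is
    not currently a free common neighbour of the flanking residues.
    """
    target = tuple(move.target)
    if target not in diagonal_candidates(conf, move.residue):
        raise ConformationError(
            f"invalid diagonal move: residue {move.residue} -> {target}"
        )
    conf.move_residue(move.residue, target)
    return conf


def _pull_displacements(
    conf: Conformation, i: int, L: Point, C, step: int
) -> Tuple[Tuple[int, Point], ...]:
    """Displacement set for a pull anchored at ``i`` toward chain index
    direction ``step`` (-1 pulls the head side, +1 the tail side).

    ``C`` is None for end-of-chain anchors and for the degenerate
    corner-flip (where the neighbour on the pulled side keeps its place).
    """
    coords = conf.coords
    disp = [(i, L)]
    if C is not None:
        disp.append((i + step, C))
        j = i + 2 * step
        while 0 <= j < len(coords):
            if is_adjacent(coords[j], disp[-1][1]):
                break
            disp.append((j, coords[j - 2 * step]))
            j += step
    return tuple(disp)


def pull_candidates(
    conf: Conformation, i: int, direction: Direction
) -> List[PullMove]:
    """All valid pull moves anchored at residue ``i`` in ``direction``.

    ``toward_head`` pulls residues with indices below ``i`` (the target
    point is a free neighbour of residue ``i+1``); ``toward_tail`` is the
    mirror image.  An end anchor (``i == 0`` toward_head, ``i == n-1``
    toward_tail) simply relocates to a free neighbour of its single chain
    neighbour.  May be empty; deterministic order by (target, first pulled
    point).
    """
    if direction not in ("toward_head", "toward_tail"):
        raise ValueError(f"unknown pull direction {direction!r}")
    n = len(conf)
    step = -1 if direction == "toward_head" else 1
    # the residue whose neighbourhood supplies the target point
    post = i - step
    if not 0 <= post < n:
        return []  # no residue to stay bonded to on that side
    occ = conf.occupancy
    old_i = conf.coords[i]
    moves: List[PullMove] = []
    for L in sorted(neighbours(conf.coords[post])):
        if L in occ:
            continue
        prev = i + step  # first residue on the pulled side
        if not 0 <= prev < n or is_adjacent(conf.coords[prev], L):
            # end anchor, or degenerate corner-flip: only residue i moves
            moves.append(
                PullMove(i, direction, _pull_displacements(conf, i, L, None, step))
            )
            continue
        for C in common_neighbours(L, old_i):
            if C in occ:
                continue
            moves.append(
                PullMove(i, direction, _pull_displacements(conf, i, L, C, step))
            )
    return moves


def apply_pull(conf: Conformation, move: PullMove) -> Conformation:
    """Apply a pull move in place and return the conformation.

    The full displacement set is validated atomically: on any violation
    (stale move, collision, broken bond) the conformation is unchanged and
    ConformationError is raised.
    """
    conf.apply_displacements(move.displacements)
    return conf


def inverse_pull(conf: Conformation, move: PullMove) -> PullMove:
    """The inverse of ``move`` relative to ``conf`` *before* application.

    Applying ``move`` and then the returned inverse restores ``conf``'s
    coordinates exactly.
    """
    return PullMove(
        residue=move.residue,
        direction=(
            "toward_tail" if move.direction == "toward_head" else "toward_head"
        ),
        displacements=tuple(
            (i, conf.coords[i]) for i, _ in move.displacements
        ),
    )
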