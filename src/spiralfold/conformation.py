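"""HP sequences and their self-avoiding embeddings on the FCC lattice.

A protein is reduced to a string over ``{H, P}``: hydrophobic residues
(Gly, Ala, Pro, Val, Leu, Ile, Met, Phe, Tyr, Trp) map to ``H`` and polar
residues (Ser, Thr, Cys, Asn, Gln, Lys, His, Arg, Asp, Glu) map to ``P``.
A conformation assigns one FCC lattice point per residue such that
consecutive residues are lattice neighbours and no point is used twice
(a self-avoiding walk).

The free energy of a conformation under the HP contact model is

    E = sum_{i < j-1} c_ij * e_ij

with ``c_ij = 1`` iff residues i and j are lattice neighbours and
non-consecutive in the chain, and ``e_ij = -1`` iff both are H (else 0).
Energy is therefore the negated count of non-consecutive H-H contacts and
is kept as an exact integer throughout.
"""

from __future__ import annotations

import random
from typing import Dict, List, Optional, Sequence

from .lattice import (
    BASIS_VECTORS,
    Point,
    FractionalPoint,
    centroid,
    is_adjacent,
    is_lattice_point,
)

__all__ = [
    "HPSequence",
    "Conformation",
    "ConformationError",
    "aa_to_hp",
    "initialise_saw",
    "evaluate",
    "energy_delta",
    "hydrophobic_core_centre",
    "structural_difference",
]


class ConformationError(ValueError):
    """A conformation invariant (self-avoidance, connectivity, bookkeeping)
    is violated, or an operation's precondition does not hold."""


# 10/10 hydrophobicity partition of the 20 standard amino acids.
_HYDROPHOBIC_1 = set("GAPVLIMFYW")
_POLAR_1 = set("STCNQKHRDE")

_THREE_TO_ONE = {
    "GLY": "G", "ALA": "A", "PRO": "P", "VAL": "V", "LEU": "L",
    "ILE": "I", "MET": "M", "PHE": "F", "TYR": "Y", "TRP": "W",
    "SER": "S", "THR": "T", "CYS": "C", "ASN": "N", "GLN": "Q",
    "LYS": "K", "HIS": "H", "ARG": "R", "ASP": "D", "GLU": "E",
}


class HPSequence:
    """An H/P string of length >= 2.

    Parameters
    ----------
    residues : str
        String over the alphabet ``{H, P}`` (case-insensitive input is
        normalised to upper case).
    """

    __slots__ = ("residues", "h_count", "h_indices")

    def __init__(self, residues: str):
        residues = str(residues).upper()
        if len(residues) < 2:
            raise ValueError("an HP sequence needs at least 2 residues")
        bad = set(residues) - {"H", "P"}
        if bad:
            raise ValueError(
                f"invalid HP sequence characters: {sorted(bad)!r}"
            )
        self.residues = residues
        self.h_indices = tuple(
            i for i, c in enumerate(residues) if c == "H"
        )
        self.h_count = len(self.h_indices)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __eq__(self, other) -> bool:
        if isinstance(other, HPSequence):
            return self.residues == other.residues
        if isinstance(other, str):
            return self.residues == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.residues)

    def __repr__(self) -> str:
        return f"HPSequence({self.residues!r})"


def as_hp_sequence(sequence) -> HPSequence:
    """Coerce a string or HPSequence to an HPSequence."""
    return sequence if isinstance(sequence, HPSequence) else HPSequence(sequence)


def aa_to_hp(amino_acids) -> HPSequence:
    """Convert an amino-acid sequence to its H/P reduction.

    Accepts a 1-letter string (``"GAVL"``), an iterable of 3-letter codes
    (``["Gly", "Ala"]``), or a whitespace/hyphen-separated string of
    3-letter codes.  Case-insensitive.

    Raises
    ------
    ValueError
        On a residue that is not one of the 20 standard amino acids; the
        message names the 1-based offending position.
    """
    if isinstance(amino_acids, str):
        stripped = amino_acids.replace("-", " ")
        if " " in stripped.strip():
            codes = stripped.split()
        else:
            codes = list(amino_acids.strip())
    else:
        codes = [str(c) for c in amino_acids]

    out = []
    for pos, code in enumerate(codes, start=1):
        c = code.strip().upper()
        if len(c) == 3:
            c = _THREE_TO_ONE.get(c, "?")
        if c in _HYDROPHOBIC_1:
            out.append("H")
        elif c in _POLAR_1:
            out.append("P")
        else:
            raise ValueError(
                f"unknown amino acid {code!r} at position {pos}"
            )
    return HPSequence("".join(out))


class Conformation:
    """An HP sequence embedded as a self-avoiding walk on the FCC lattice.

    Attributes
    ----------
    sequence : HPSequence
    coords : list of (x, y, z) int tuples
        ``coords[i]`` is the lattice point of residue ``i``.
    occupancy : dict mapping point -> residue index
        Exact inverse of ``coords``; the O(1) collision/contact index.
    """

    __slots__ = ("sequence", "coords", "occupancy")

    def __init__(self, sequence, coords: Sequence[Point], validate: bool = True):
        self.sequence = as_hp_sequence(sequence)
        self.coords: List[Point] = [tuple(p) for p in coords]
        self.occupancy: Dict[Point, int] = {
            p: i for i, p in enumerate(self.coords)
        }
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.coords)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Conformation):
            return NotImplemented
        return (
            self.sequence.residues == other.sequence.residues
            and self.coords == other.coords
        )

    def __repr__(self) -> str:
        return (
            f"<Conformation n={len(self)} "
            f"H={self.sequence.h_count} E={evaluate(self)}>"
        )

    def copy(self) -> "Conformation":
        """Independent deep copy (coords and occupancy are rebuilt)."""
        return Conformation(self.sequence, list(self.coords), validate=False)

    def is_free(self, p: Point) -> bool:
        return p not in self.occupancy

    def move_residue(self, i: int, target: Point) -> None:
        """Low-level in-place relocation of residue ``i`` to a free point.

        Does not re-check chain connectivity; callers (the move operators)
        are responsible for the chain invariants.
        """
        if target in self.occupancy:
            raise ConformationError(f"target {target} is occupied")
        del self.occupancy[self.coords[i]]
        self.coords[i] = tuple(target)
        self.occupancy[self.coords[i]] = i

    def apply_displacements(self, displacements) -> None:
        """Atomically relocate several residues; validates, then commits.

        ``displacements`` is an iterable of ``(index, point)`` pairs.  On
        any invariant violation the conformation is left unchanged.
        """
        new_coords = list(self.coords)
        for i, p in displacements:
            new_coords[i] = tuple(p)
        candidate = Conformation(self.sequence, new_coords, validate=False)
        candidate.validate()  # raises ConformationError, self untouched
        self.coords = candidate.coords
        self.occupancy = candidate.occupancy

    def validate(self) -> None:
        """Raise ConformationError on any violated invariant."""
        n = len(self.sequence)
        if len(self.coords) != n:
            raise ConformationError(
                f"{len(self.coords)} coordinates for {n} residues"
            )
        seen: Dict[Point, int] = {}
        for i, p in enumerate(self.coords):
            if len(p) != 3 or not all(isinstance(c, int) for c in p):
                raise ConformationError(f"residue {i}: non-integer point {p}")
            if not is_lattice_point(p):
                raise ConformationError(
                    f"residue {i}: point {p} is off the even-sum FCC sublattice"
                )
            if p in seen:
                raise ConformationError(
                    f"self-avoidance violated: residues {seen[p]} and {i} "
                    f"both at {p}"
                )
            seen[p] = i
        for i in range(n - 1):
            if not is_adjacent(self.coords[i], self.coords[i + 1]):
                raise ConformationError(
                    f"connectivity violated between residues {i} and {i + 1}"
                )
        if self.occupancy != seen:
            raise ConformationError("occupancy index inconsistent with coords")


def initialise_saw(
    sequence,
    rng: random.Random,
    max_attempts: int = 10_000,
) -> Conformation:
    """Grow a random self-avoiding walk for ``sequence``.

    Residue 0 is placed at the origin; each successive residue goes to a
    uniformly chosen free neighbour of its predecessor.  A dead end (no
    free neighbour) restarts the whole walk from scratch on the same rng
    stream; dead ends are rare on the 12-way FCC lattice.

    Raises
    ------
    ConformationError
        If ``max_attempts`` restarts are exhausted (practically
        unreachable for chains up to ~1000 residues).
    """
    seq = as_hp_sequence(sequence)
    n = len(seq)
    for _ in range(max_attempts):
        coords: List[Point] = [(0, 0, 0)]
        occupied = {(0, 0, 0)}
        for _i in range(1, n):
            x, y, z = coords[-1]
            free = [
                (x + dx, y + dy, z + dz)
                for dx, dy, dz in BASIS_VECTORS
                if (x + dx, y + dy, z + dz) not in occupied
            ]
            if not free:
                break
            p = free[rng.randrange(len(free))]
            coords.append(p)
            occupied.add(p)
        else:
            return Conformation(seq, coords, validate=False)
    raise ConformationError(
        f"failed to build a self-avoiding walk in {max_attempts} attempts"
    )


def evaluate(conf: Conformation) -> int:
    """HP free energy: minus the number of non-consecutive H-H contacts."""
    seq = conf.sequence.residues
    occ = conf.occupancy
    energy = 0
    for i in conf.sequence.h_indices:
        x, y, z = conf.coords[i]
        for dx, dy, dz in BASIS_VECTORS:
            j = occ.get((x + dx, y + dy, z + dz))
            # count each pair once (j > i + 1 also excludes consecutive)
            if j is not None and j > i + 1 and seq[j] == "H":
                energy -= 1
    return energy


def energy_delta(conf: Conformation, i: int, target: Point) -> int:
    """Energy change of relocating residue ``i`` to ``target``.

    Computed from residue ``i``'s local contacts only; only H-H contacts
    carry energy, so moving a P residue always yields 0.

    Raises
    ------
    ConformationError
        If ``target`` is occupied or the move would break chain adjacency.
    """
    target = tuple(target)
    if target in conf.occupancy:
        raise ConformationError(f"target {target} is occupied")
    n = len(conf)
    for j in (i - 1, i + 1):
        if 0 <= j < n and not is_adjacent(conf.coords[j], target):
            raise ConformationError(
                f"moving residue {i} to {target} breaks the bond to {j}"
            )
    seq = conf.sequence.residues
    if seq[i] != "H":
        return 0
    occ = conf.occupancy

    def h_contacts(point: Point) -> int:
        x, y, z = point
        count = 0
        for dx, dy, dz in BASIS_VECTORS:
            j = occ.get((x + dx, y + dy, z + dz))
            if j is not None and abs(j - i) > 1 and seq[j] == "H":
                count += 1
        return count

    # E = -contacts, and only contacts involving residue i change.
    return h_contacts(conf.coords[i]) - h_contacts(target)


def hydrophobic_core_centre(conf: Conformation) -> FractionalPoint:
    """Arithmetic mean of the H-residue coordinates (the dynamic HCC).

    Raises
    ------
    ValueError
        For an all-P sequence, whose core centre is undefined.
    """
    if conf.sequence.h_count == 0:
        raise ValueError(
            "hydrophobic core centre undefined for an all-P sequence"
        )
    return centroid(conf.coords[i] for i in conf.sequence.h_indices)


def structural_difference(a: Conformation, b: Conformation) -> float:
    """Fraction of residues placed at different points in ``a`` and ``b``.

    Positionwise, without superposition: all moves in this package are
    local and both conformations share the residue-0 anchor.
    """
    if a.sequence.residues != b.sequence.residues:
        raise ValueError("structural_difference requires the same sequence")
    n = len(a)
    return sum(1 for i in range(n) if a.coords[i] != b.coords[i]) / n
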