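"""Stagnation recovery: pull-move random walks and relay-restart.

A premature hydrophobic core traps the spiral search in a local minimum.
Two escape mechanisms are used on demand:

* ``random_walk`` applies pull moves at uniformly random anchors until the
  conformation is structurally diverse from the trapped one (10-75% of
  residues displaced) while staying close in energy (relative change of
  5-10%).  If the windows cannot be hit within the pull budget, the
  best-effort visited conformation is returned.

* ``relay_restart`` restarts the search from a random member of the top
  fraction (default 10%) of an archive holding every global-best
  ("improving") solution seen so far; the chosen entry is re-queued to the
  bottom of the archive so it is not immediately reselected.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .conformation import (
    Conformation,
    evaluate,
    structural_difference,
)
from .moves import apply_pull, pull_candidates

__all__ = [
    "WalkParams",
    "WalkResult",
    "ImprovingSolutionList",
    "random_walk",
    "relay_restart",
]


@dataclass(frozen=True)
class WalkParams:
    """Acceptance windows and budget for the pull-move random walk.

    energy_window : (lo, hi)
        Accepted band for |E - E_start| / max(1, |E_start|).
    structure_window : (lo, hi)
        Accepted band for the fraction of displaced residues.
    max_pulls : int or None
        Attempt budget; ``None`` means ``50 * n`` for an n-residue chain.
    """

    energy_window: Tuple[float, float] = (0.05, 0.10)
    structure_window: Tuple[float, float] = (0.10, 0.75)
    max_pulls: Optional[int] = None

    def __post_init__(self):
        for name in ("energy_window", "structure_window"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.max_pulls is not None and self.max_pulls < 1:
            raise ValueError("max_pulls must be >= 1")


@dataclass
class WalkResult:
    """Outcome of a random walk.

    ``satisfied`` is True when both windows were hit; ``moved`` is False
    only when no pull move could be applied at all (input returned
    unchanged).
    """

    conformation: Conformation
    pulls: int
    satisfied: bool
    moved: bool


def _window_violation(value: float, window: Tuple[float, float]) -> float:
    lo, hi = window
    if value < lo:
        return lo - value
    if value > hi:
        return value - hi
    return 0.0


def random_walk(
    conf: Conformation,
    params: WalkParams,
    rng: random.Random,
) -> WalkResult:
    """Perturb ``conf`` by random pull moves into the acceptance windows.

    Anchors and pull directions are drawn uniformly; among the valid pull
    moves of the drawn (anchor, direction) one is chosen uniformly.  After
    each applied pull, the relative energy change from the starting energy
    and the structural difference from the starting conformation are
    tested against the windows; the first conformation inside both is
    returned.  On budget exhaustion the visited conformation minimising
    (energy-window violation, then structure-window violation) is returned
    as a best-effort escape.  ``conf`` itself is never mutated.
    """
    original = conf
    work = conf.copy()
    e_start = evaluate(conf)
    n = len(conf)
    budget = params.max_pulls if params.max_pulls is not None else 50 * n

    best_effort: Optional[Tuple[float, float, Conformation]] = None
    pulls = 0
    for _ in range(budget):
        anchor = rng.randrange(n)
        direction = ("toward_head", "toward_tail")[rng.randrange(2)]
        cands = pull_candidates(work, anchor, direction)
        if not cands:
            continue
        move = cands[rng.randrange(len(cands))]
        apply_pull(work, move)
        pulls += 1
        energy = evaluate(work)
        rel_e = abs(energy - e_start) / max(1, abs(e_start))
        diff = structural_difference(original, work)
        e_viol = _window_violation(rel_e, params.energy_window)
        s_viol = _window_violation(diff, params.structure_window)
        if e_viol == 0.0 and s_viol == 0.0:
            return WalkResult(work, pulls, satisfied=True, moved=True)
        if best_effort is None or (e_viol, s_viol) < best_effort[:2]:
            best_effort = (e_viol, s_viol, work.copy())
    if pulls == 0:
        # nothing could move: flag and hand the input back unchanged
        return WalkResult(original.copy(), 0, satisfied=False, moved=False)
    assert best_effort is not None
    return WalkResult(best_effort[2], pulls, satisfied=False, moved=True)


@dataclass
class _ArchiveEntry:
    conformation: Conformation
    energy: int
    stamp: int  # insertion counter, for post-run inspection


class ImprovingSolutionList:
    """Ordered archive of global-best conformations, newest at the top.

    Entries are pushed only on strict improvement over the best energy
    ever recorded, so at push time energies strictly decrease from the
    bottom (oldest) to the top (newest); entries re-queued to the bottom
    by relay-restart are exempt from that ordering and identifiable by
    their insertion stamp.
    """

    def __init__(self, capacity: Optional[int] = None):
        if capacity is not None and capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.entries: List[_ArchiveEntry] = []
        self._best_pushed: Optional[int] = None
        self._stamp = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def best_energy(self) -> Optional[int]:
        return self._best_pushed

    def record_improvement(self, conf: Conformation, energy: int) -> None:
        """Snapshot a new global best at the top of the list.

        Raises ValueError on a non-improving push — a bookkeeping bug in
        the caller, never a legitimate state.
        """
        if self._best_pushed is not None and energy >= self._best_pushed:
            raise ValueError(
                f"non-improving push: {energy} vs best {self._best_pushed}"
            )
        self.entries.insert(0, _ArchiveEntry(conf.copy(), energy, self._stamp))
        self._stamp += 1
        self._best_pushed = energy
        if self.capacity is not None and len(self.entries) > self.capacity:
            self.entries.pop()  # evict the bottom (oldest / re-queued)

    def snapshot(self) -> List[Tuple[int, int]]:
        """(energy, insertion stamp) pairs, top to bottom."""
        return [(e.energy, e.stamp) for e in self.entries]


def relay_restart(
    archive: ImprovingSolutionList,
    fraction: float,
    rng: random.Random,
) -> Conformation:
    """Draw a restart conformation from the archive's top fraction.

    ``k = max(1, ceil(fraction * len))`` entries at the top are eligible;
    one is chosen uniformly, moved to the bottom of the list (out of the
    scope of near-future reselection), and an independent copy of its
    conformation is returned.
    """
    if len(archive) == 0:
        raise ValueError("relay restart from an empty archive")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = max(1, math.ceil(fraction * len(archive)))
    entry = archive.entries.pop(rng.randrange(k))
    archive.entries.append(entry)
    return entry.conformation.copy()
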