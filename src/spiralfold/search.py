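"""The tabu-guided spiral search (SS-Tabu) main loop.

Each iteration first tries an H-move: for every non-tabu hydrophobic
residue with both chain neighbours, the free common neighbours of its
flanks are ranked by Cartesian distance to the dynamic hydrophobic-core
centre (HCC, the mean of all H coordinates); a residue enters the H-move
list only if its best corner-flip target is strictly nearer the HCC than
its current position, and the globally nearest listed candidate is
applied.  The moved residue then becomes tabu for ``10 + hCount // 10``
iterations.  When no H-move exists, one sweep of P-moves runs instead:
each polar residue in chain order gets a uniformly random free corner-flip
(no HCC, no ranking, no tabu).  Moves are accepted on the distance
heuristic alone — energy is evaluated for bookkeeping, never as a gate.

Stagnation handling: after ``walk_trigger`` iterations without a new
global best, a pull-move random walk perturbs the current conformation;
after ``restart_trigger`` consecutive walks without a new global best, the
search relay-restarts from the archive of improving solutions (the tabu
list is cleared on restart, kept across walks).
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

from .conformation import (
    Conformation,
    HPSequence,
    as_hp_sequence,
    energy_delta,
    evaluate,
    hydrophobic_core_centre,
    initialise_saw,
)
from .lattice import Point, distance
from .moves import DiagonalMove, apply_diagonal, diagonal_candidates
from .recovery import (
    ImprovingSolutionList,
    WalkParams,
    random_walk,
    relay_restart,
)

__all__ = [
    "RunConfig",
    "TabuState",
    "MoveCandidate",
    "SearchState",
    "LogRow",
    "tabu_tenure",
    "select_move_for_h",
    "select_and_apply_p_moves",
    "spiral_step",
    "run",
    "run_many",
]


def tabu_tenure(h_count: int) -> int:
    """Tabu tenure as a function of the hydrophobic residue count:
    ``10 + floor(h_count / 10)``."""
    if h_count < 0:
        raise ValueError("h_count must be >= 0")
    return 10 + h_count // 10


@dataclass
class RunConfig:
    """Budgets and knobs for one search run.

    At least one of ``max_iterations`` and ``time_budget`` (seconds) must
    be set.  ``stop_energy`` stops the run early once the global best
    reaches a known bound.  Walk windows follow the published recovery
    recipe: relative energy change within 5-10%, structural change within
    10-75%.
    """

    seed: int = 0
    max_iterations: Optional[int] = None
    time_budget: Optional[float] = None
    walk_trigger: int = 200
    restart_trigger: int = 3
    energy_window: Tuple[float, float] = (0.05, 0.10)
    structure_window: Tuple[float, float] = (0.10, 0.75)
    max_pulls: Optional[int] = None
    archive_fraction: float = 0.1
    archive_capacity: Optional[int] = None
    stop_energy: Optional[int] = None

    def validate(self) -> None:
        if self.max_iterations is None and self.time_budget is None:
            raise ValueError("set max_iterations and/or time_budget")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.time_budget is not None and self.time_budget <= 0:
            raise ValueError("time_budget must be positive")
        if self.walk_trigger < 1:
            raise ValueError("walk_trigger must be >= 1")
        if self.restart_trigger < 1:
            raise ValueError("restart_trigger must be >= 1")
        if not 0 < self.archive_fraction <= 1:
            raise ValueError("archive_fraction must be in (0, 1]")
        # window sanity is delegated to WalkParams
        self.walk_params()

    def walk_params(self) -> WalkParams:
        return WalkParams(
            energy_window=tuple(self.energy_window),
            structure_window=tuple(self.structure_window),
            max_pulls=self.max_pulls,
        )


class TabuState:
    """Per-hydrophobic-residue tabu bookkeeping.

    A residue moved at iteration ``t`` is barred from H-move selection at
    iterations ``t+1 … t+tenure-1`` and eligible again at ``t+tenure``.
    """

    def __init__(self, tenure: int):
        self.tenure = tenure
        self.expiry: dict[int, int] = {}

    def is_tabu(self, residue: int, iteration: int) -> bool:
        return self.expiry.get(residue, iteration) > iteration

    def mark(self, residue: int, iteration: int) -> None:
        self.expiry[residue] = iteration + self.tenure

    def clear(self) -> None:
        self.expiry.clear()


@dataclass(frozen=True)
class MoveCandidate:
    """An HCC-improving corner-flip candidate for an H residue."""

    residue: int
    target: Point
    dist: float


LogRow = Tuple[int, int, int, str]  # iteration, energy, best energy, event


@dataclass
class SearchState:
    """Mutable state of one spiral-search run."""

    sequence: HPSequence
    config: RunConfig
    rng: random.Random
    current: Conformation
    energy: int
    best: Conformation
    best_energy: int
    tabu: TabuState
    archive: ImprovingSolutionList
    iteration: int = 0
    non_improving: int = 0
    failed_walks: int = 0
    walks: int = 0
    restarts: int = 0
    log: List[LogRow] = field(default_factory=list)

    def _log(self, event: str) -> None:
        self.log.append((self.iteration, self.energy, self.best_energy, event))


def initial_state(sequence, config: RunConfig) -> SearchState:
    """Initialise a run: seeded rng, random self-avoiding walk, archive."""
    config.validate()
    seq = as_hp_sequence(sequence)
    rng = random.Random(config.seed)
    conf = initialise_saw(seq, rng)
    energy = evaluate(conf)
    archive = ImprovingSolutionList(capacity=config.archive_capacity)
    archive.record_improvement(conf, energy)
    state = SearchState(
        sequence=seq,
        config=config,
        rng=rng,
        current=conf,
        energy=energy,
        best=conf.copy(),
        best_energy=energy,
        tabu=TabuState(tabu_tenure(seq.h_count)),
        archive=archive,
    )
    state._log("init")
    return state


def select_move_for_h(state: SearchState) -> Optional[MoveCandidate]:
    """Pick the H-move that most tightens the hydrophobic core.

    Recomputes the HCC, then for every non-tabu interior H residue finds
    its nearest-to-HCC free corner-flip target; the residue is listed only
    if that target is strictly nearer the HCC than its current position.
    Returns the listed candidate with the globally smallest distance (ties
    broken by residue index, then by target point), or None when the list
    is empty.
    """
    seq = state.sequence
    if seq.h_count == 0:
        raise ValueError("H-move selection undefined for an all-P sequence")
    conf = state.current
    n = len(conf)
    hcc = hydrophobic_core_centre(conf)
    best: Optional[MoveCandidate] = None
    for i in seq.h_indices:
        if i == 0 or i == n - 1 or state.tabu.is_tabu(i, state.iteration):
            continue
        targets = diagonal_candidates(conf, i)
        if not targets:
            continue
        # nearest target; lexicographic candidate order settles dist ties
        t_best = min(targets, key=lambda t: (distance(t, hcc), t))
        d_best = distance(t_best, hcc)
        if d_best >= distance(conf.coords[i], hcc):
            continue
        cand = MoveCandidate(i, t_best, d_best)
        if best is None or (cand.dist, cand.residue, cand.target) < (
            best.dist, best.residue, best.target
        ):
            best = cand
    return best


def select_and_apply_p_moves(state: SearchState) -> int:
    """One sweep of random corner-flips over the polar residues.

    Visits P residues in chain order; each one with at least one free
    common neighbour of its flanks gets a uniformly chosen one applied.
    No HCC, no distance ranking, no tabu.  Returns the number applied.
    (P relocations never change the HP energy: only H-H contacts count.)
    """
    conf = state.current
    n = len(conf)
    applied = 0
    for i, residue in enumerate(state.sequence.residues):
        if residue != "P" or i == 0 or i == n - 1:
            continue
        targets = diagonal_candidates(conf, i)
        if not targets:
            continue
        target = targets[state.rng.randrange(len(targets))]
        apply_diagonal(conf, DiagonalMove(i, target))
        applied += 1
    return applied


def _note_improvement(state: SearchState) -> None:
    if state.energy < state.best_energy:
        state.best = state.current.copy()
        state.best_energy = state.energy
        state.archive.record_improvement(state.best, state.best_energy)
        state.non_improving = 0
        state.failed_walks = 0
    else:
        state.non_improving += 1


def spiral_step(state: SearchState) -> SearchState:
    """One iteration: an H-move if one exists, else a P-move sweep."""
    cand = select_move_for_h(state) if state.sequence.h_count else None
    if cand is not None:
        delta = energy_delta(state.current, cand.residue, cand.target)
        apply_diagonal(state.current, DiagonalMove(cand.residue, cand.target))
        state.tabu.mark(cand.residue, state.iteration)
        state.energy += delta
        event = "H"
    else:
        select_and_apply_p_moves(state)
        event = "P"
    state.iteration += 1
    _note_improvement(state)
    state._log(event)
    return state


def _recover(state: SearchState) -> None:
    """Random-walk, or relay-restart once walks have repeatedly failed."""
    config = state.config
    if state.failed_walks >= config.restart_trigger and len(state.archive):
        state.current = relay_restart(
            state.archive, config.archive_fraction, state.rng
        )
        state.energy = evaluate(state.current)
        state.tabu.clear()
        state.failed_walks = 0
        state.restarts += 1
        event = "restart"
    else:
        result = random_walk(state.current, config.walk_params(), state.rng)
        state.current = result.conformation
        state.energy = evaluate(state.current)
        state.failed_walks += 1
        state.walks += 1
        event = "walk"
    # a perturbation can stumble onto a new global best: keep bookkeeping exact
    if state.energy < state.best_energy:
        state.best = state.current.copy()
        state.best_energy = state.energy
        state.archive.record_improvement(state.best, state.best_energy)
        state.failed_walks = 0
    state.non_improving = 0
    state._log(event)


def run(sequence, config: RunConfig) -> SearchState:
    """Run the spiral search to its budget and return the final state.

    The returned state carries the best conformation and energy, the
    archive of improving solutions, and the full run log (iteration,
    current energy, best energy, event).
    """
    state = initial_state(sequence, config)
    started = time.monotonic()
    while True:
        if (
            config.max_iterations is not None
            and state.iteration >= config.max_iterations
        ):
            break
        if (
            config.time_budget is not None
            and time.monotonic() - started >= config.time_budget
        ):
            break
        if (
            config.stop_energy is not None
            and state.best_energy <= config.stop_energy
        ):
            break
        if state.non_improving >= config.walk_trigger:
            _recover(state)
            continue
        spiral_step(state)
    return state


def run_many(sequence, config: RunConfig, runs: int) -> List[SearchState]:
    """Independent sequential runs seeded ``seed, seed+1, …, seed+runs-1``."""
    if runs < 1:
        raise ValueError("runs must be >= 1")
    return [
        run(sequence, replace(config, seed=config.seed + k))
        for k in range(runs)
    ]
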