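# Methods

## Model

Conformations live on the face-centred-cubic lattice realised as the
even-coordinate-sum sublattice of ℤ³.  Every point has 12 neighbours at
squared Euclidean distance 2, reached by the basis vectors
(±1,±1,0), (0,±1,±1), (±1,0,±1).  The first residue is anchored at the
origin; since every basis vector has even coordinate sum, the even-sum
invariant holds chain-wide and all geometry stays in exact integers.
Chains are strictly self-avoiding walks: one point per residue, bonded
residues adjacent.

Energy is the HP contact potential: −1 per pair of non-consecutive
hydrophobic residues that are lattice neighbours, 0 otherwise.  It is
stored as an integer contact count (negated) throughout — there is no
floating-point energy anywhere, so no tolerance questions arise.  During
the search the energy is maintained incrementally from the moved residue's
local contacts; the equivalence with a full recount is enforced by an
oracle test over tens of thousands of random moves.  Relocating a polar
residue can never change the energy (only H positions enter the contact
sum), which the P-move sweep exploits by skipping evaluation bookkeeping
per move.

## Search procedure

Each iteration:

1. **H-move selection.**  Recompute the hydrophobic-core centre (HCC) as
   the mean of the H-residue coordinates.  For every hydrophobic residue
   that has both chain neighbours and is not tabu, collect the free common
   neighbours of its flanks, take the one nearest the HCC, and shortlist
   the residue iff that target is *strictly* nearer the HCC than its
   current position.  Apply the shortlisted move with the globally
   smallest target–HCC distance.  The moved residue becomes tabu for
   `10 + hCount // 10` iterations (integer floor division; tenure must be
   integral and this is the conventional reading of hCount/10).
2. **P-move sweep** (only when no H-move exists): each polar interior
   residue, in chain order, gets one uniformly random free corner-flip if
   any exists.  No HCC, no ranking, no tabu.

Acceptance is energy-blind: moves are taken on the distance heuristic
alone, and energy is evaluated only to track the incumbent and the global
best.  The best-energy trace is therefore non-increasing by bookkeeping,
not by move acceptance.

Tie-breaking is fully deterministic: candidate targets are enumerated in
lexicographic point order, the per-residue best target breaks distance
ties lexicographically, and the global winner breaks ties by (distance,
residue index, target point).  All randomness flows from a single seeded
`random.Random` stream, making entire runs bit-reproducible from
(sequence, config): this is asserted end-to-end on run logs and final
coordinates.

### Stagnation recovery

After `walk_trigger` consecutive iterations without a new global best, a
**pull-move random walk** perturbs the incumbent: uniformly random anchor
and direction, uniformly random valid pull move, repeated until the
conformation sits inside both acceptance windows — relative energy change
|E − E_start| / max(1, |E_start|) within 5–10% and structural difference
(fraction of displaced residues, positionwise without superposition — all
moves are local and both conformations share the residue-0 anchor) within
10–75%.  The energy band is interpreted two-sided on the pre-walk energy;
the max(1, ·) normaliser keeps it defined at E_start = 0.  If the windows
are not hit within the pull budget (default 50·n attempts), the visited
conformation minimising (energy-window violation, then structure-window
violation) is returned as a best-effort escape, which guarantees
termination.  A fully blocked chain (no pull applies at all) returns the
input flagged.

After `restart_trigger` consecutive walks without a new global best, a
**relay-restart** replaces the incumbent with a random member of the top
`archive_fraction` (ceil, minimum 1) of the improving-solution archive —
the list of every global best since initialisation, newest on top.  The
chosen entry is re-queued to the bottom so it cannot be reselected until
enough new improvements push it back into the top fraction.  Archived
entries are deep snapshots; later search mutations can never corrupt them.
The tabu list is cleared on relay-restart (a genuinely new trajectory) but
kept across random walks (a perturbation of the same trajectory).

### Pull moves on FCC

The pull move is defined in the literature on the square lattice; the
lattice-generic construction used here is: pulling the head side of anchor
*i*, choose a free target L adjacent to residue *i+1*; if residue *i−1* is
already adjacent to L the move degenerates to a corner-flip of *i* alone;
otherwise choose a free intermediate C among the common neighbours of L
and the old position of *i*, set new(i) = L, new(i−1) = C, and for
j = i−2, i−3, … set new(j) = old(j+2) until the chain is already adjacent
or the end is consumed (tail pulls mirror this; end anchors are plain end
flips).  Every candidate is represented as its explicit displacement set,
which makes the inverse trivial (swap in the pre-move coordinates) and
application atomic: the displaced set is validated as a whole and the
conformation is untouched on any violation.  Locality, validity and exact
reversibility are enforced by a 10,000-move randomised soak test.

## Initialisation

A random self-avoiding walk: residue 0 at the origin, each successive
residue at a uniformly chosen *free* neighbour of its predecessor.  A dead
end restarts the whole walk on the same random stream (up to 10,000
attempts).  With 12-way branching, dead ends are rare and plain restart is
unbiased enough for an initial solution; backtracking would add complexity
for no practical gain at the chain lengths involved.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `walk_trigger` | 200 iterations | non-improving iterations before a random walk |
| `restart_trigger` | 3 walks | failed walks before a relay-restart |
| `energy_window` | (0.05, 0.10) | accepted relative energy change of a walk |
| `structure_window` | (0.10, 0.75) | accepted displaced-residue fraction of a walk |
| `max_pulls` | 50·n | walk attempt budget |
| `archive_fraction` | 0.1 | top fraction of the archive eligible for restart |
| `archive_capacity` | unbounded | optional cap, oldest-evicting |
| tabu tenure | 10 + hCount // 10 | iterations a moved H residue stays barred |

The walk windows and the tenure formula are the published recipe; the
stagnation triggers are not published anywhere and the defaults here are
the package's own choice — small enough that desk-scale runs (10⁴–10⁵
iterations) cycle through walk and restart many times, large enough that
the spiral phase can finish squeezing a core between escapes.  Budgets are
`max_iterations` and/or a wall-clock `time_budget`; an optional
`stop_energy` halts a run that reaches a known bound, natural for a
benchmark whose instances carry energy lower bounds.

Degenerate inputs are defined, not errors: an all-P sequence has no HCC,
so the search runs P-sweeps only and reports energy 0; 2-mers have no
interior residues and simply idle to their budget.

## Synthetic sequences

The benchmark sequences are external and not redistributable, so tests
and examples use generated HP sequences: exact H count
`round(n · h_fraction)` placed by a seeded shuffle (never independent coin
flips, so a spec determines its sequence), optionally grouped into runs of
a given block length to mimic the consecutive-H segments that drive core
formation in real HP reductions.  What the generator does **not** emulate:
the long-range H/P correlation structure of real proteins, designed-in
native states, or instance-specific lower bounds.  Passing search tests on
synthetic chains therefore demonstrate mechanism correctness (validity,
monotone bookkeeping, reproducibility, energy improvement), not benchmark
competitiveness on the published instances, which required multi-hour runs
per instance.

## Benchmark analysis

The packaged fixtures transcribe the published per-instance energy tables:
best/average energies of LS-Mem, LS-Tabu and SS-Tabu with the known lower
bounds (21 instances), and the relay-restart ablation (12 instances).
Relative improvement is recomputed from these energies and displayed to
two decimals with half-up rounding, matching the published formatting.
Three published S-block figures (23.52, 37.03, 25.92) were printed with
the third decimal truncated rather than rounded (the exact values are
23.529…, 37.037…, 25.926…); the printed-RI fixture records the rounding
style per row, and the tests assert agreement under the style actually
used.  The per-comparison ranges — 12.20–37.68% vs LS-Mem, 21.95–75.00%
vs LS-Tabu, 1.39–23.08% for relay-restart — are reproduced exactly.
Instances with an unknown lower bound (3on7) or without a reference result
(LS-Mem on the F90/S blocks) are reported as not computable and excluded
from ranges.  RI is invariant under a common shift of all three energies
(it is a ratio of differences), which is property-tested.

## Test problem sizes

The suite works at desk scale by design: geometry oracles enumerate
brute-force neighbour sets over thousands of random pairs; move soaks run
10,000 mixed diagonal/pull moves on 50-mers with full validation and
round-trip checks; search sanity uses a 6-mer whose global optimum (−7,
an octahedral H-cluster: 12 edges minus 5 chain bonds) is found by
exhaustive enumeration with the first bond fixed by lattice symmetry, and
a 48-mer one-minute run checked for strict improvement.  Campaign-scale
behaviour (hours per instance on 90–279-mers) is reachable through the
same `RunConfig` but is not exercised by the tests.

## Known limitations

* The comparison baselines (LS-Mem, LS-Tabu) are consumed as published
  numbers; they are not re-implemented.
* Single move repertoire (diagonal + pull); no crankshaft, rotation or
  regrowth moves, no side chains, no energy models beyond HP.
* The H-move heuristic is greedy on distance and never gates on energy; on
  very small or H-poor chains progress relies heavily on walks/restarts.
* `structural_difference` is anchor-dependent by construction; it is not a
  superposition RMSD and is not comparable across unrelated embeddings.
* Sequential runs only; multi-run campaigns derive seeds as
  `seed, seed+1, …` and run one after another.
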