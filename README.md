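# spiralfold

Hydrophobic-core directed tabu spiral search (SS-Tabu) for simplified
*ab initio* protein structure prediction: the hydrophobic–polar (HP)
energy model on the 3D face-centred-cubic (FCC) lattice.

## The problem and the model

In the HP model the 20 amino acids are split into hydrophobic
(Gly, Ala, Pro, Val, Leu, Ile, Met, Phe, Tyr, Trp → **H**) and polar
(Ser, Thr, Cys, Asn, Gln, Lys, His, Arg, Asp, Glu → **P**) classes.  A
conformation is a self-avoiding walk on the FCC lattice — realised here as
the even-coordinate-sum sublattice of ℤ³, where each point has 12
neighbours — with one lattice point per residue.  Its free energy is

    E = Σ_{i<j−1} c_ij · e_ij

where `c_ij = 1` iff residues *i*, *j* are non-consecutive lattice
neighbours and `e_ij = −1` iff both are H (else 0): minimising E means
packing a maximally dense hydrophobic core.  Finding the minimum is the
combinatorial heart of lattice protein structure prediction and is NP-hard.

The spiral search attacks it with a single move operator — the diagonal
move (corner-flip) of residue *i* to a free common neighbour of residues
*i−1* and *i+1* — guided by a dynamic **hydrophobic-core centre** (HCC),
the arithmetic mean of all H-residue coordinates:

    x_hcc = (1/n_h) Σ x_i   (and likewise y, z)

Each iteration the non-tabu H residue whose best corner-flip target lies
nearest the HCC (and strictly nearer than its current position) is moved,
then barred for a tenure of `10 + hCount/10` iterations; when no such
H-move exists, each polar residue in turn gets a uniformly random
corner-flip.  Stagnation is escaped by a pull-move random walk (target:
5–10% relative energy change with 10–75% of residues displaced) and, when
walks repeatedly fail, by a *relay-restart* from a random member of the
top 10% of the archive of all improving solutions seen so far.

The package also ships the relative-improvement (RI) benchmark analysis.
With `E_t`/`E_r` the average energies of a target/reference method and
`E_1` the instance's known lower bound of free energy,

    RI = (E_t − E_r) / (E_1 − E_r) × 100%

measures how much of the reference's remaining gap to the bound the
target closes — the fair comparison when methods operate near the bound.

## Worked example

```python
import spiralfold as sf
from spiralfold.generate import SyntheticSpec, generate_hp_sequence

seq = generate_hp_sequence(SyntheticSpec(length=48, h_fraction=0.5, seed=1))
# -> PHPHHPHHHPPPPPHPPHHHHHPPHHHPPHPPHPPHPHHPPPPHHHPH

states = sf.run_many(seq, sf.RunConfig(seed=7, max_iterations=20_000), 3)
for s in states:
    print(f"seed {s.config.seed}: best {s.best_energy} after {s.iteration} "
          f"iterations ({s.walks} walks, {s.restarts} restarts)")
summary = sf.summarize_runs([s.best_energy for s in states])
print("best:", summary.best, "avg:", round(summary.average, 2))
```

prints

```
seed 7: best -60 after 20000 iterations (78 walks, 19 restarts)
seed 8: best -66 after 20000 iterations (78 walks, 19 restarts)
seed 9: best -61 after 20000 iterations (76 walks, 21 restarts)
best: -66 avg: -62.33
```

i.e. three independent seeded runs on a synthetic 48-mer (24 H residues)
reach conformations with 60–66 non-consecutive H-H contacts' worth of
energy; `best` is the campaign minimum and `avg` the per-run mean, the two
statistics used in benchmark tables.  Each run's `state.best` is a
validated conformation and `state.log` the full per-iteration trace.

The same from the shell, plus the benchmark analysis:

```sh
spiralfold fold --seq PHPHHPHHHPPPPPHPPHHHHHPPHHHPPHPPHPPHPHHPPPPHHHPH \
    --seed 7 --runs 3 --max-iterations 20000 --out-dir out/
spiralfold gen -n 20 --h-fraction 0.5 --seed 4   # synthetic_4  PPPPHPPPHHHHPHHPPHHH
spiralfold ri                                    # RI tables + ranges
spiralfold validate out/seq1_seed7_best.tsv      # invariant check
```

`spiralfold ri` recomputes the published RI columns from the packaged
benchmark-energy tables and ends each comparison with its range, e.g.
`range: 12.20% to 37.68%` for SS-Tabu vs LS-Mem.

The 21 standard benchmark instances (F90/S/F180/R blocks and six
CASP-target HP reductions) are registered with their sizes and known
energy lower bounds in `spiralfold.io.load_instances`; their sequences are
external and are attached from user-supplied files, never redistributed.

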