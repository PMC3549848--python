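"""Synthetic HP-sequence generation.

The benchmark sequences are external (not redistributable), so tests and
examples use synthetic sequences with a controlled hydrophobic fraction.
The H count is exact — ``round(n * h_fraction)`` — placed by a seeded
shuffle rather than independent coin flips, so a spec fully determines
its sequence.  An optional block length groups the H residues into runs,
mimicking the segments of consecutive hydrophobics that drive core
formation in real HP reductions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .conformation import HPSequence

__all__ = ["SyntheticSpec", "generate_hp_sequence"]


@dataclass(frozen=True)
class SyntheticSpec:
    length: int
    h_fraction: float = 0.5
    seed: int = 0
    block_length: Optional[int] = None

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if not 0.0 <= self.h_fraction <= 1.0:
            raise ValueError("h_fraction must be in [0, 1]")
        if self.block_length is not None and self.block_length < 1:
            raise ValueError("block_length must be >= 1")


def generate_hp_sequence(spec: SyntheticSpec) -> HPSequence:
    """Deterministically generate an HP sequence from ``spec``."""
    rng = random.Random(spec.seed)
    n = spec.length
    n_h = round(n * spec.h_fraction)
    if spec.block_length is None:
        letters = ["H"] * n_h + ["P"] * (n - n_h)
        rng.shuffle(letters)
        return HPSequence("".join(letters))
    # group the H residues into runs, then shuffle runs among single P's
    b = spec.block_length
    runs = ["H" * b] * (n_h // b)
    if n_h % b:
        runs.append("H" * (n_h % b))
    items = runs + ["P"] * (n - n_h)
    rng.shuffle(items)
    return HPSequence("".join(items))
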