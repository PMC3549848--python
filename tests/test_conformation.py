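"""Sequences, embeddings, energy evaluation, and the core centre."""

import random

import pytest
from hypothesis import given, strategies as st

from spiralfold.conformation import (
    Conformation,
    ConformationError,
    HPSequence,
    aa_to_hp,
    energy_delta,
    evaluate,
    hydrophobic_core_centre,
    initialise_saw,
    structural_difference,
)
from spiralfold.lattice import is_adjacent, is_lattice_point
from spiralfold.moves import diagonal_candidates

from conftest import random_conformation


class TestHPSequence:
    def test_counts_h_residues(self):
        seq = HPSequence("HPHHPP")
        assert seq.h_count == 3
        assert seq.h_indices == (0, 2, 3)

    @pytest.mark.parametrize("bad", ["", "H", "HX", "hq"])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            HPSequence(bad)

    def test_case_normalised(self):
        assert HPSequence("hpH").residues == "HPH"


class TestAaToHp:
    @pytest.mark.parametrize(
        "aa,expected",
        [
            ("GAVL", "HHHH"),
            ("STCN", "PPPP"),
            ("GAPVLIMFYW", "HHHHHHHHHH"),
            ("STCNQKHRDE", "PPPPPPPPPP"),
            ("gavlst", "HHHHPP"),
        ],
    )
    def test_one_letter(self, aa, expected):
        assert aa_to_hp(aa).residues == expected

    def test_three_letter_codes(self):
        assert aa_to_hp(["Gly", "Ser", "TRP", "glu"]).residues == "HPHP"
        assert aa_to_hp("Gly Ala Ser Thr").residues == "HHPP"

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            aa_to_hp("GX")
        with pytest.raises(ValueError, match="position 3"):
            aa_to_hp(["Gly", "Ala", "Xyz"])


class TestInitialiseSaw:
    def test_deterministic_under_seed(self):
        a = initialise_saw("HPHPHPHPHP", random.Random(7))
        b = initialise_saw("HPHPHPHPHP", random.Random(7))
        assert a.coords == b.coords

    def test_dimer_contract(self):
        conf = initialise_saw("HH", random.Random(0))
        assert conf.coords[0] == (0, 0, 0)
        assert is_adjacent(conf.coords[0], conf.coords[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_ninety_mer_walks_are_valid(self, seed):
        rng = random.Random(seed)
        for _ in range(60):
            conf = initialise_saw("HP" * 45, rng)
            conf.validate()
            assert all(is_lattice_point(p) for p in conf.coords)


class TestEvaluate:
    def test_worked_square_has_one_contact(self, worked_square):
        assert evaluate(worked_square) == -1

    def test_dimer_zero(self):
        conf = Conformation(HPSequence("HH"), [(0, 0, 0), (1, 1, 0)])
        assert evaluate(conf) == 0

    def test_all_polar_zero(self, worked_square):
        conf = Conformation(HPSequence("PPPP"), worked_square.coords)
        assert evaluate(conf) == 0

    def test_never_positive_and_counts_contacts(self):
        for seed in range(20):
            conf = random_conformation("HHPHHPHPHH" * 3, seed)
            e = evaluate(conf)
            assert e <= 0
            # independent O(n^2) pair count
            brute = 0
            seq = conf.sequence.residues
            for i in range(len(conf)):
                for j in range(i + 2, len(conf)):
                    if (
                        seq[i] == seq[j] == "H"
                        and is_adjacent(conf.coords[i], conf.coords[j])
                    ):
                        brute -= 1
            assert e == brute

    @given(st.sampled_from([(2, 0, 0), (0, -2, 2), (4, 2, -2), (-6, 0, 0)]))
    def test_translation_invariance(self, shift):
        conf = random_conformation("HHPHHPHH", 3)
        moved = Conformation(
            conf.sequence,
            [(x + shift[0], y + shift[1], z + shift[2]) for x, y, z in conf.coords],
        )
        assert evaluate(moved) == evaluate(conf)


class TestEnergyDelta:
    def test_matches_full_reevaluation(self, rng):
        checked = 0
        for seed in range(40):
            conf = random_conformation("HHPHPHHPPHHHPHPH", seed)
            for i in range(1, len(conf) - 1):
                for target in diagonal_candidates(conf, i):
                    before = evaluate(conf)
                    delta = energy_delta(conf, i, target)
                    after = conf.copy()
                    after.move_residue(i, target)
                    assert delta == evaluate(after) - before
                    checked += 1
        assert checked > 200

    def test_polar_moves_are_energy_neutral(self):
        for seed in range(10):
            conf = random_conformation("HPPPPPPPPH", seed)
            for i in range(1, len(conf) - 1):
                for target in diagonal_candidates(conf, i):
                    assert energy_delta(conf, i, target) == 0

    def test_occupied_target_rejected(self, worked_square):
        with pytest.raises(ConformationError, match="occupied"):
            energy_delta(worked_square, 1, worked_square.coords[3])

    def test_chain_breaking_target_rejected(self, worked_square):
        with pytest.raises(ConformationError, match="bond"):
            energy_delta(worked_square, 1, (9, 9, 0))


class TestHydrophobicCoreCentre:
    def test_single_h(self):
        conf = Conformation(HPSequence("PH"), [(0, 0, 0), (1, 1, 0)])
        assert hydrophobic_core_centre(conf) == (1.0, 1.0, 0.0)

    def test_midpoint_of_two_h(self):
        conf = Conformation(
            HPSequence("HPH"), [(0, 0, 0), (1, 1, 0), (2, 0, 0)]
        )
        assert hydrophobic_core_centre(conf) == (1.0, 0.0, 0.0)

    def test_translation_linearity(self):
        conf = random_conformation("HHPHPH", 1)
        shifted = Conformation(
            conf.sequence, [(x + 2, y, z + 2) for x, y, z in conf.coords]
        )
        cx, cy, cz = hydrophobic_core_centre(conf)
        assert hydrophobic_core_centre(shifted) == pytest.approx(
            (cx + 2, cy, cz + 2)
        )

    def test_all_polar_is_undefined(self):
        conf = Conformation(HPSequence("PP"), [(0, 0, 0), (1, 1, 0)])
        with pytest.raises(ValueError):
            hydrophobic_core_centre(conf)


class TestStructuralDifference:
    def test_identity(self, worked_square):
        assert structural_difference(worked_square, worked_square) == 0.0

    def test_single_residue_move(self, worked_square):
        other = worked_square.copy()
        other.move_residue(1, (1, 0, 1))  # another common neighbour
        assert structural_difference(worked_square, other) == 0.25

    def test_three_of_four_moved(self, worked_square):
        other = Conformation(
            worked_square.sequence,
            [(0, 0, 0), (1, 0, 1), (2, 0, 2), (1, 0, 3)],
        )
        assert structural_difference(worked_square, other) == 0.75

    def test_requires_same_sequence(self, worked_square):
        other = Conformation(HPSequence("PPPP"), worked_square.coords)
        with pytest.raises(ValueError):
            structural_difference(worked_square, other)


class TestValidator:
    def test_detects_duplicate_point(self):
        with pytest.raises(ConformationError, match="self-avoidance"):
            Conformation(
                HPSequence("HHH"), [(0, 0, 0), (1, 1, 0), (0, 0, 0)]
            )

    def test_detects_broken_chain(self):
        with pytest.raises(ConformationError, match="connectivity"):
            Conformation(HPSequence("HH"), [(0, 0, 0), (4, 0, 0)])

    def test_detects_off_lattice_point(self):
        with pytest.raises(ConformationError, match="sublattice"):
            Conformation(HPSequence("HH"), [(0, 0, 0), (1, 0, 0)])
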