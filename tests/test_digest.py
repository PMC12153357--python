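"""Proteome handling, digestion, modification expansion, sequon scanning."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from glycopen.digest import (
    Peptide,
    Protein,
    digest,
    expand_modifications,
    find_sequons,
    make_decoys,
    peptide_neutral_mass,
    read_fasta,
    write_fasta,
)

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=80)


# ---------------------------------------------------------------------------
# FASTA


class TestFasta:
    def test_read_two_record_fixture(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">P1 first protein\nMKAGR\nTESTK\n>P2\nAAAA\n")
        proteins = read_fasta(path)
        assert [p.accession for p in proteins] == ["P1", "P2"]
        assert proteins[0].sequence == "MKAGRTESTK"
        assert proteins[0].description == "first protein"
        assert len(proteins[1]) == 4

    def test_lowercase_residues_uppercased(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">P1\nmkagr\n")
        assert read_fasta(path)[0].sequence == "MKAGR"

    def test_duplicate_accession_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">P1\nMK\n>P1\nAA\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_round_trip(self, tmp_path):
        proteins = [Protein("A1", "MKAGRTESTK", "demo"), Protein("A2", "NVSNKT")]
        path = tmp_path / "rt.fasta"
        write_fasta(proteins, path)
        back = read_fasta(path)
        assert [(p.accession, p.sequence) for p in back] == [
            (p.accession, p.sequence) for p in proteins
        ]

    def test_decoys_are_reversed_and_prefixed(self):
        decoys = make_decoys([Protein("P1", "MKAGR")])
        assert decoys[0].accession == "rev_P1"
        assert decoys[0].sequence == "RGAKM"
        assert decoys[0].decoy


# ---------------------------------------------------------------------------
# Digestion


class TestDigest:
    def test_tryptic_full_specific(self):
        peptides = digest(Protein("P", "MKAGRTESTK"), max_missed=0,
                          specificity="full", min_length=2)
        assert {p.sequence for p in peptides} == {"MK", "AGR", "TESTK"}

    def test_proline_suppression(self):
        peptides = digest(Protein("P", "AKRPGK"), max_missed=0,
                          specificity="full", min_length=2)
        assert {p.sequence for p in peptides} == {"AK", "RPGK"}

    def test_no_proline_suppression_when_disabled(self):
        peptides = digest(Protein("P", "AKRPGK"), max_missed=0,
                          specificity="full", min_length=2, suppress_proline=False)
        assert {p.sequence for p in peptides} == {"AK", "R", "PGK"} - {"R"}

    def test_empty_protein(self):
        assert digest(Protein("P", "")) == []

    def test_missed_cleavages_counted(self):
        peptides = digest(Protein("P", "MKAGRTESTK"), max_missed=1,
                          specificity="full", min_length=2)
        by_seq = {p.sequence: p for p in peptides}
        assert by_seq["MKAGR"].missed_cleavages == 1
        assert by_seq["AGRTESTK"].missed_cleavages == 1
        assert by_seq["MK"].missed_cleavages == 0

    def test_semi_n_ragged_is_superset_with_enzymatic_c_terminus(self):
        protein = Protein("P", "MKAGRTESTKAAAR")
        full = {p.sequence for p in digest(protein, specificity="full", min_length=3)}
        semi_peps = digest(protein, specificity="semi-N-ragged", min_length=3)
        semi = {p.sequence for p in semi_peps}
        assert full <= semi
        assert "ESTK" in semi  # ragged N-terminus, enzymatic C-terminus
        for p in semi_peps:
            assert p.sequence[-1] in "KR" or p.end == len(protein.sequence)

    @given(sequences)
    @settings(max_examples=60, deadline=None)
    def test_zero_missed_full_peptides_tile_the_protein(self, seq):
        peptides = digest(Protein("P", seq), max_missed=0, specificity="full",
                          min_length=1, max_length=10**6)
        assert "".join(p.sequence for p in peptides) == seq

    def test_peptide_slice_matches_parent(self):
        protein = Protein("P", "MKAGRTESTKAAAR")
        for p in digest(protein, specificity="semi-N-ragged", min_length=3):
            assert protein.sequence[p.start - 1 : p.end] == p.sequence


# ---------------------------------------------------------------------------
# Modifications and masses


class TestModifications:
    def test_oxidation_expansion_keeps_fixed_cam(self):
        pep = Peptide("ACMK", "P", 2, 5, 0)
        states = expand_modifications(pep)
        assert len(states) == 2
        for state in states:
            assert any(name == "Carbamidomethyl" for _, name, _ in state.mods)
        assert sorted(len(s.mods) for s in states) == [1, 2]

    def test_unmodifiable_peptide_single_state(self):
        states = expand_modifications(Peptide("AGLK", "P", 10, 13, 0))
        assert len(states) == 1 and states[0].mods == ()

    def test_two_met_single_variable_slot(self):
        states = expand_modifications(Peptide("MM", "P", 5, 6, 0), max_variable=1)
        assert len(states) == 3  # none, Ox@1, Ox@2

    def test_nterm_acetyl_only_on_protein_start(self):
        at_start = expand_modifications(Peptide("AGLK", "P", 1, 4, 0))
        inside = expand_modifications(Peptide("AGLK", "P", 3, 6, 0))
        assert len(at_start) == 2 and len(inside) == 1
        assert any(pos == 0 for s in at_start for pos, _, _ in s.mods)


class TestNeutralMass:
    @pytest.mark.parametrize(
        "peptide, expected",
        [
            (Peptide("G", "P", 1, 1, 0), 75.0320),
            (Peptide("C", "P", 1, 1, 0,
                     mods=((1, "Carbamidomethyl", 57.02146),)), 178.0412),
        ],
    )
    def test_reference_masses(self, peptide, expected):
        assert peptide_neutral_mass(peptide) == pytest.approx(expected, abs=1e-3)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_neutral_mass("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_neutral_mass("AXK")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_pyteomics(self, seq):
        """Independent oracle: pyteomics' peptide mass calculator."""
        assert peptide_neutral_mass(seq) == pytest.approx(
            pyteomics_mass.fast_mass(seq), abs=2e-3
        )

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
           st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_concatenation_additivity(self, a, b):
        """mass(A+B) = mass(A) + mass(B) - water (one peptide bond)."""
        water = 18.0105646
        assert peptide_neutral_mass(a + b) == pytest.approx(
            peptide_neutral_mass(a) + peptide_neutral_mass(b) - water, abs=1e-6
        )


# ---------------------------------------------------------------------------
# Sequons


class TestSequons:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ANATS", [2]),
            ("ANPTS", []),   # X = P excluded
            ("NVSNKT", [1, 4]),
            ("NVS", [1]),
            ("NV", []),      # window beyond the terminus
            ("", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert find_sequons(seq) == expected

    @given(sequences)
    @settings(max_examples=1000, deadline=None)
    def test_agrees_with_regex_oracle(self, seq):
        oracle = [m.start() + 1 for m in re.finditer(r"(?=N[^P][ST])", seq)]
        assert find_sequons(seq) == oracle
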