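"""Proteome handling, in-silico digestion and sequon scanning.

Implements the search-space side of the pipeline: FASTA records, combined
trypsin/LysC digestion with semi-specific N-ragged cleavage, expansion of
fixed and variable modifications, peptide neutral masses, reversed-sequence
decoys, and the N-X-S/T (X != P) sequon scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import WATER_MASS

#: Monoisotopic residue masses (Da), 5 dp.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

AMINO_ACIDS = "".join(sorted(RESIDUE_MASS))

#: Modification deltas (Da).
MOD_DELTAS = {
    "Carbamidomethyl": 57.02146,
    "Oxidation": 15.99491,
    "Acetyl": 42.01057,
}

DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class Protein:
    accession: str
    sequence: str
    description: str = ""
    decoy: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable modification and where it may occur."""

    name: str
    delta: float
    targets: frozenset[str]  # residue letters; 'protein-nterm' for N-terminus
    fixed: bool = False


#: The modification set used throughout: carbamidomethyl-Cys fixed,
#: Met oxidation and protein N-terminal acetylation variable.
DEFAULT_MODS = (
    ModificationSpec("Carbamidomethyl", MOD_DELTAS["Carbamidomethyl"],
                     frozenset("C"), fixed=True),
    ModificationSpec("Oxidation", MOD_DELTAS["Oxidation"], frozenset("M")),
    ModificationSpec("Acetyl", MOD_DELTAS["Acetyl"], frozenset({"protein-nterm"})),
)


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with its cleavage provenance and modification state.

    ``mods`` maps 1-based residue index (0 for the peptide N-terminus) to
    (modification name, delta Da). ``start``/``end`` are 1-based inclusive
    coordinates on the parent protein.
    """

    sequence: str
    accession: str
    start: int
    end: int
    missed_cleavages: int
    semi: bool = False  # True when the N-terminus is non-enzymatic
    mods: tuple[tuple[int, str, float], ...] = ()
    decoy: bool = False

    @property
    def mod_mass(self) -> float:
        return sum(delta for _, _, delta in self.mods)

    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[Protein]:
    """Read a FASTA proteome; headers split at first whitespace.

    Sequences are uppercased; duplicate accessions are rejected.
    """
    proteins: list[Protein] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        seen.add(acc)
        desc = rec.description[len(acc):].strip() if rec.description.startswith(acc) else rec.description
        proteins.append(Protein(acc, str(rec.seq).upper(), desc,
                                decoy=acc.startswith(DECOY_PREFIX)))
    return proteins


def write_fasta(proteins: list[Protein], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.description)
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def make_decoys(proteins: list[Protein]) -> list[Protein]:
    """Full-sequence-reversal decoys with accession prefix ``rev_``."""
    return [
        Protein(DECOY_PREFIX + p.accession, p.sequence[::-1],
                "reversed decoy", decoy=True)
        for p in proteins
        if not p.decoy
    ]


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str, suppress_proline: bool = True) -> list[int]:
    """0-based positions after which trypsin/LysC cleaves (C-term of K/R)."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR":
            if suppress_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    protein: Protein,
    max_missed: int = 3,
    specificity: str = "semi-N-ragged",
    min_length: int = 5,
    max_length: int = 50,
    suppress_proline: bool = True,
) -> list[Peptide]:
    """Digest a protein with the combined trypsin/LysC rule.

    ``specificity`` is ``'full'`` (both termini enzymatic) or
    ``'semi-N-ragged'`` (the C-terminus enzymatic, the N-terminus allowed to
    be ragged: every suffix of a full-specific peptide is also emitted).
    Length bounds are inclusive; duplicates (same coordinates) are removed.
    """
    if specificity not in ("full", "semi-N-ragged"):
        raise ValueError(f"unknown specificity {specificity!r}")
    seq = protein.sequence
    if not seq:
        return []
    sites = cleavage_sites(seq, suppress_proline)
    # Segment boundaries: [start, end) fragments between consecutive sites.
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    peptides: dict[tuple[int, int], Peptide] = {}

    def emit(start0: int, end0: int, missed: int, semi: bool) -> None:
        length = end0 - start0
        if not (min_length <= length <= max_length):
            return
        key = (start0, end0)
        if key in peptides:
            return
        peptides[key] = Peptide(
            sequence=seq[start0:end0],
            accession=protein.accession,
            start=start0 + 1,
            end=end0,
            missed_cleavages=missed,
            semi=semi,
            decoy=protein.decoy,
        )

    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for j in range(i, min(i + max_missed + 1, n_seg)):
            start0, end0 = bounds[i], bounds[j + 1]
            missed = j - i
            emit(start0, end0, missed, semi=False)
            if specificity == "semi-N-ragged":
                for ragged in range(start0 + 1, end0):
                    emit(ragged, end0, missed, semi=True)
    return sorted(peptides.values(), key=lambda p: (p.start, p.end))


def expand_modifications(
    peptide: Peptide,
    specs: tuple[ModificationSpec, ...] = DEFAULT_MODS,
    max_variable: int = 2,
) -> list[Peptide]:
    """Enumerate modification states of a peptide.

    Fixed modifications are applied to every state; variable modifications
    are combined combinatorially up to ``max_variable`` total occurrences.
    Protein N-terminal acetylation is only offered on peptides starting at
    residue 1, at most once.
    """
    fixed: list[tuple[int, str, float]] = []
    variable_slots: list[tuple[int, str, float]] = []
    for spec in specs:
        if "protein-nterm" in spec.targets:
            if peptide.start == 1:
                variable_slots.append((0, spec.name, spec.delta))
            continue
        for idx, aa in enumerate(peptide.sequence, start=1):
            if aa in spec.targets:
                (fixed if spec.fixed else variable_slots).append((idx, spec.name, spec.delta))

    states = []
    for k in range(0, min(max_variable, len(variable_slots)) + 1):
        for combo in itertools.combinations(variable_slots, k):
            mods = tuple(sorted(fixed + list(combo)))
            states.append(replace(peptide, mods=mods))
    return states


def peptide_neutral_mass(peptide: Peptide | str) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    if isinstance(peptide, str):
        seq, mod_mass = peptide, 0.0
    else:
        seq, mod_mass = peptide.sequence, peptide.mod_mass
    if not seq:
        raise ValueError("empty peptide sequence")
    try:
        residue_sum = sum(RESIDUE_MASS[aa] for aa in seq)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} has no defined mass") from None
    return residue_sum + WATER_MASS + mod_mass


# ---------------------------------------------------------------------------
# Sequon scanning


def find_sequons(sequence: str) -> list[int]:
    """1-based Asn positions in N-X-S/T sequons, X any residue except Pro."""
    return [
        i + 1
        for i in range(len(sequence) - 2)
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in "ST"
    ]
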