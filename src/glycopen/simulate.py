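"""Ground-truthed synthetic glycoproteomes and MS/MS spectra.

The generator emulates the statistical structure the downstream analysis
assumes: a proteome dominated by unmodified tryptic peptides, one large
S-layer-like glycoprotein carrying a predominant Asn-linked glycan on most
of its N-X-S/T sequons, a decoy (false) modification placed on off-sequon
asparagines whose spectra carry no sugar oxonium ions, and uniform noise
peaks. Every emitted spectrum has exactly one truth record, so pipeline
output can be scored against known ground truth.

Proteins are assembled from random tryptic segments (internal residues free
of K/R, a K/R terminus), which guarantees every planted sequon sits inside a
clean fully tryptic peptide of reasonable length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import HEXASACCHARIDE, PROTON_MASS, glycan_mass, oxonium_mz
from .digest import Peptide, Protein, digest, expand_modifications, find_sequons
from .ions import by_ladder, cz_ladder, residue_masses
from .spectra import Spectrum

#: Residues used inside tryptic segments (no K/R so segment boundaries are
#: the only cleavage sites; no C to keep fixed-mod bookkeeping out of the
#: truth tables). Asn occurs freely; accidental sequons are scrubbed so the
#: only N-X-S/T motifs are the planted ones, and the remaining off-sequon
#: asparagines serve as decoy-modification carriers.
_SEGMENT_ALPHABET = list("ADEFGHILMNPQSTVWY")

GLYCAN_NAME = "hexasaccharide"
DECOY_MOD_NAME = "false_631"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe the reference scenario: one 1,199-residue S-layer-like
    protein with six sequons, five of them occupied by the 1,650.64 Da
    hexasaccharide; a 631.26 Da false modification on off-sequon Asn with no
    oxonium ions; 2+/3+ precursors; log-normal fragment intensities; 3 ppm
    precursor / 5 ppm fragment mass error; uniform noise peaks.
    """

    seed: int = 0
    n_background_proteins: int = 20
    background_length: tuple[int, int] = (200, 400)
    slayer_length: int = 1199
    n_sequons: int = 6
    n_glycosylated: int = 5
    glycoform_blocks: tuple[str, ...] = HEXASACCHARIDE
    decoy_mod_mass: float = 631.26
    n_spectra: int = 2000
    #: Spectrum category fractions: glycopeptide, decoy-modified, plain
    #: S-layer, plain background (must sum to 1).
    fractions: tuple[float, float, float, float] = (0.15, 0.05, 0.20, 0.60)
    charge_probs: tuple[float, float] = (0.5, 0.5)  # P(z=2), P(z=3)
    ladder_completeness: float = 0.85
    noise_peaks: int = 30
    intensity_log10_sd: float = 0.5
    oxonium_boost: float = 2.0
    precursor_ppm_sd: float = 3.0
    fragment_ppm_sd: float = 5.0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("spectrum category fractions must sum to 1")
        if not 0.0 <= self.ladder_completeness <= 1.0:
            raise ValueError("ladder_completeness must be in [0, 1]")
        if self.n_glycosylated > self.n_sequons:
            raise ValueError("cannot glycosylate more sequons than exist")

    @property
    def glycan_delta(self) -> float:
        return glycan_mass(self.glycoform_blocks)


@dataclass(frozen=True)
class TruthRecord:
    spectrum_id: str
    peptide: str
    accession: str
    charge: int
    mod_name: str | None = None  # None for unmodified spectra
    mod_delta: float = 0.0
    mod_site: int = 0  # 1-based residue index within the peptide; 0 if none

    def to_row(self) -> dict:
        return {
            "spectrum_id": self.spectrum_id,
            "peptide": self.peptide,
            "accession": self.accession,
            "charge": self.charge,
            "mod_name": self.mod_name or "",
            "mod_delta": self.mod_delta,
            "mod_site": self.mod_site,
        }


def write_truth(records: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame([r.to_row() for r in records]).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# Proteome simulation


def _random_segment(rng: np.random.Generator, length: int) -> list[str]:
    """A tryptic segment: random non-K/R residues ending in K or R.

    The first residue is never proline, so the preceding cleavage site is
    never suppressed and every segment boundary stays cleavable.
    """
    body = list(rng.choice(_SEGMENT_ALPHABET, size=length - 1))
    if body and body[0] == "P":
        body[0] = "A"
    return body + [str(rng.choice(["K", "R"]))]


def _sequon_segment(rng: np.random.Generator, length: int) -> tuple[list[str], int]:
    """A tryptic segment with one N-X-S/T sequon; returns (segment, N offset)."""
    seg = _random_segment(rng, length)
    pos = int(rng.integers(2, length - 4))  # keep the motif fully internal
    seg[pos] = "N"
    seg[pos + 1] = str(rng.choice([a for a in "ADEFGV"]))
    seg[pos + 2] = str(rng.choice(["S", "T"]))
    return seg, pos


def _scrub_unplanned_sequons(seq: list[str], planned: set[int]) -> None:
    """Mutate the +2 residue of any unplanned N-X-S/T motif to Ala in place."""
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST" and (i + 1) not in planned:
            seq[i + 2] = "A"


def _build_protein(
    rng: np.random.Generator,
    accession: str,
    target_length: int,
    n_sequons: int = 0,
    description: str = "",
) -> tuple[Protein, list[int]]:
    # Plan segment lengths to sum exactly to the target length.
    seg_lengths: list[int] = []
    remaining = target_length
    while remaining > 29:
        length = int(rng.integers(8, 22))
        seg_lengths.append(length)
        remaining -= length
    if remaining > 21:  # split the tail into two mid-sized segments
        seg_lengths.extend([remaining // 2, remaining - remaining // 2])
    elif remaining > 0:
        seg_lengths.append(remaining)
    segments = [_random_segment(rng, length) for length in seg_lengths]

    sequon_positions: list[int] = []
    if n_sequons:
        # Spread sequon-bearing segments evenly along the protein; the last
        # planted sequon sits near the C-terminus (the site that will stay
        # unoccupied in the reference scenario, mimicking a terminal sequon
        # that is never observed glycosylated).
        n_seg = len(segments)
        chosen = np.linspace(1, n_seg - 2, n_sequons).round().astype(int)
        if len(set(chosen)) < n_sequons:
            chosen = rng.choice(np.arange(1, n_seg - 1), size=n_sequons, replace=False)
            chosen.sort()
        offsets = np.concatenate([[0], np.cumsum(seg_lengths)[:-1]])
        for seg_idx in chosen:
            seg, pos = _sequon_segment(rng, seg_lengths[seg_idx])
            segments[seg_idx] = seg
            sequon_positions.append(int(offsets[seg_idx] + pos + 1))  # 1-based

    seq = [aa for seg in segments for aa in seg]
    _scrub_unplanned_sequons(seq, set(sequon_positions))
    protein = Protein(accession, "".join(seq), description)
    assert find_sequons(protein.sequence) == sorted(sequon_positions)
    return protein, sorted(sequon_positions)


def simulate_proteome(config: SimConfig) -> tuple[list[Protein], dict]:
    """Generate the synthetic proteome and its sequon manifest.

    Returns the protein list (S-layer protein first) and a manifest mapping
    accession -> {"sequons": [...], "glycosylated": [...]} (1-based Asn
    positions). Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    proteins: list[Protein] = []
    manifest: dict[str, dict] = {}

    if config.slayer_length:
        if config.n_sequons * 3 > config.slayer_length:
            raise ValueError("sequon plan infeasible for protein length")
        slayer, sequons = _build_protein(
            rng, "SLP_0001", config.slayer_length, config.n_sequons,
            description="S-layer-like glycoprotein",
        )
        proteins.append(slayer)
        manifest[slayer.accession] = {
            "sequons": sequons,
            "glycosylated": sequons[: config.n_glycosylated],
        }

    for i in range(config.n_background_proteins):
        length = int(rng.integers(*config.background_length))
        prot, _ = _build_protein(rng, f"BKG_{i + 1:04d}", length,
                                 description="background protein")
        proteins.append(prot)
        manifest[prot.accession] = {"sequons": [], "glycosylated": []}
    return proteins, manifest


# ---------------------------------------------------------------------------
# Spectrum simulation


def _tryptic_pool(protein: Protein) -> list[Peptide]:
    """Fully tryptic, fixed-mod-applied peptides (no missed cleavages)."""
    return [
        expand_modifications(p, max_variable=0)[0]
        for p in digest(protein, max_missed=0, specificity="full")
    ]


def _peptide_for_site(pool: list[Peptide], site: int) -> Peptide:
    for pep in pool:
        if pep.start <= site <= pep.end:
            return pep
    raise ValueError(f"no tryptic peptide covers residue {site}")


def _sample_intensities(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    return 10.0 ** rng.normal(0.0, sd, size=n)


def _make_spectrum(
    rng: np.random.Generator,
    config: SimConfig,
    spectrum_id: str,
    peptide: Peptide,
    charge: int,
    mod_delta: float = 0.0,
    mod_site: int = 0,
    oxonium: bool = False,
) -> Spectrum:
    neutral = peptide.neutral_mass() + mod_delta
    precursor = (neutral + charge * PROTON_MASS) / charge
    precursor *= 1.0 + rng.normal(0.0, config.precursor_ppm_sd) * 1e-6

    masses = residue_masses(peptide)
    b, y = by_ladder(masses)
    peaks = [b, y, np.array([peptide.neutral_mass() + PROTON_MASS])]  # Y0-style
    if mod_delta:
        # EThcD-style c/z ions retain the modification at its site.
        c, z = cz_ladder(residue_masses(peptide, site_delta=(mod_site, mod_delta)))
        peaks.extend([c, z])
    mz = np.concatenate(peaks)
    keep = rng.random(len(mz)) < config.ladder_completeness
    mz = mz[keep]
    intensity = _sample_intensities(rng, len(mz), config.intensity_log10_sd)

    if oxonium:
        ox_mz = np.array([oxonium_mz("HexNAc"), oxonium_mz("HexNAc_frag")])
        ox_int = _sample_intensities(rng, 2, config.intensity_log10_sd) * config.oxonium_boost
        mz = np.concatenate([mz, ox_mz])
        intensity = np.concatenate([intensity, ox_int])

    mz = mz * (1.0 + rng.normal(0.0, config.fragment_ppm_sd, size=len(mz)) * 1e-6)

    if config.noise_peaks and len(intensity):
        floor = np.quantile(intensity, 0.2)
        noise_mz = rng.uniform(100.0, max(2000.0, precursor), size=config.noise_peaks)
        noise_int = rng.uniform(0.0, floor, size=config.noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_int])

    return Spectrum(spectrum_id, precursor, charge, mz, intensity)


def simulate_spectra(
    proteins: list[Protein], manifest: dict, config: SimConfig
) -> tuple[list[Spectrum], list[TruthRecord]]:
    """Simulate MS/MS spectra with one truth record per spectrum.

    Spectrum categories (glycopeptide / decoy-modified / plain S-layer /
    plain background) are drawn per spectrum from ``config.fractions``.
    Glycopeptide spectra carry the glycoform delta on a glycosylated sequon
    Asn plus oxonium ions; decoy-modified spectra carry the false delta on
    an off-sequon Asn and omit oxonium ions.
    """
    if not proteins:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)

    slayer = proteins[0]
    glyco_sites = manifest[slayer.accession]["glycosylated"]
    slayer_pool = _tryptic_pool(slayer)
    background_pool = [
        pep for prot in proteins[1:] for pep in _tryptic_pool(prot)
    ]
    # Decoy-modification carriers: background peptides with an off-sequon Asn.
    decoy_pool = [
        (pep, pep.sequence.index("N") + 1)
        for pep in background_pool
        if "N" in pep.sequence
    ]
    if not background_pool:
        background_pool = slayer_pool

    spectra: list[Spectrum] = []
    truths: list[TruthRecord] = []
    categories = rng.choice(4, size=config.n_spectra, p=list(config.fractions))
    charges = rng.choice([2, 3], size=config.n_spectra, p=list(config.charge_probs))

    for i, (cat, z) in enumerate(zip(categories, charges)):
        sid = f"scan={i + 1}"
        z = int(z)
        if cat == 0 and glyco_sites:  # glycopeptide
            site = int(rng.choice(glyco_sites))
            pep = _peptide_for_site(slayer_pool, site)
            pep_site = site - pep.start + 1
            delta = config.glycan_delta
            spectra.append(_make_spectrum(rng, config, sid, pep, z, delta, pep_site, oxonium=True))
            truths.append(TruthRecord(sid, pep.sequence, pep.accession, z,
                                      GLYCAN_NAME, delta, pep_site))
        elif cat == 1 and decoy_pool:  # false modification, off-sequon
            pep, pep_site = decoy_pool[int(rng.integers(len(decoy_pool)))]
            delta = config.decoy_mod_mass
            spectra.append(_make_spectrum(rng, config, sid, pep, z, delta, pep_site, oxonium=False))
            truths.append(TruthRecord(sid, pep.sequence, pep.accession, z,
                                      DECOY_MOD_NAME, delta, pep_site))
        else:  # unmodified
            pool = slayer_pool if cat == 2 else background_pool
            pep = pool[int(rng.integers(len(pool)))]
            spectra.append(_make_spectrum(rng, config, sid, pep, z))
            truths.append(TruthRecord(sid, pep.sequence, pep.accession, z))
    return spectra, truths
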