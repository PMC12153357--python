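"""Glycan validation, glycosite mapping and NSAF quantification.

A modification mass discovered by open searching is accepted as a bona fide
glycan only when the population of PSMs supporting it satisfies three
criteria: (i) sugar oxonium ions are present in the supporting MS/MS
spectra, (ii) localized sites conform to the conserved N-X-S/T sequon, and
(iii) the carrier peptides arise from proper enzymatic cleavage. Validated
glycoPSMs are then mapped along their proteins (per-residue coverage, site
status per sequon), proteins are quantified by the normalized spectral
abundance factor, and the per-protein glycosylation frequency is reported
as residues per confirmed site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import DIAGNOSTIC_OXONIUM_MZ
from .digest import Protein, find_sequons
from .search import PSM
from .spectra import Spectrum


@dataclass(frozen=True)
class ValidationParams:
    #: Fraction of supporting evidence each criterion must reach.
    fraction: float = 0.8
    #: Minimum supporting PSMs to call a modification bona fide.
    min_psms: int = 5
    #: ppm tolerance for detecting oxonium peaks.
    oxonium_ppm: float = 20.0
    oxonium_mz: tuple[float, ...] = DIAGNOSTIC_OXONIUM_MZ


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of the three-criterion test for one modification mass."""

    mass: float
    n_psms: int
    oxonium_present: bool
    sequon_conform: bool
    proper_cleavage: bool
    oxonium_fraction: float
    sequon_fraction: float
    cleavage_fraction: float

    @property
    def bona_fide(self) -> bool:
        return (
            self.n_psms > 0
            and self.oxonium_present
            and self.sequon_conform
            and self.proper_cleavage
        )


def _has_oxonium(spectrum: Spectrum, params: ValidationParams) -> bool:
    for mz in params.oxonium_mz:
        tol = mz * params.oxonium_ppm * 1e-6
        i = np.searchsorted(spectrum.mz, mz - tol)
        if i < len(spectrum.mz) and spectrum.mz[i] <= mz + tol:
            return True
    return False


def validate_modification(
    mass: float,
    glyco_psms: Sequence[PSM],
    spectra: Mapping[str, Spectrum],
    proteins: Mapping[str, Protein],
    params: ValidationParams | None = None,
) -> ValidationVerdict:
    """Apply the three bona fide glycan criteria to one modification mass.

    Each criterion is evaluated over the supporting PSM population and
    passes when at least ``params.fraction`` of the evidence agrees:
    (i) a registered oxonium peak in the supporting spectrum, (ii) the
    localized site on an N-X-S/T sequon of the parent protein (unlocalized
    PSMs abstain), (iii) an enzymatic peptide C-terminus (K/R or the protein
    C-terminus, consistent with semi-N-ragged searching).
    """
    params = params or ValidationParams()
    psms = list(glyco_psms)
    if not psms:
        return ValidationVerdict(mass, 0, False, False, False, 0.0, 0.0, 0.0)

    n_ox = sum(_has_oxonium(spectra[p.spectrum_id], params) for p in psms)
    ox_frac = n_ox / len(psms)

    localized = [p for p in psms if p.site]
    n_seq = 0
    for p in localized:
        prot = proteins[p.peptide.accession.removeprefix("rev_")]
        if p.protein_site in find_sequons(prot.sequence):
            n_seq += 1
    seq_frac = n_seq / len(localized) if localized else 0.0

    n_enz = 0
    for p in psms:
        prot = proteins[p.peptide.accession.removeprefix("rev_")]
        c_term_ok = (
            p.peptide.end == len(prot.sequence)
            or p.peptide.sequence[-1] in "KR"
        )
        n_enz += c_term_ok
    enz_frac = n_enz / len(psms)

    enough = len(psms) >= params.min_psms
    return ValidationVerdict(
        mass=mass,
        n_psms=len(psms),
        oxonium_present=enough and ox_frac >= params.fraction,
        sequon_conform=enough and bool(localized) and seq_frac >= params.fraction,
        proper_cleavage=enough and enz_frac >= params.fraction,
        oxonium_fraction=ox_frac,
        sequon_fraction=seq_frac,
        cleavage_fraction=enz_frac,
    )


# ---------------------------------------------------------------------------
# Glycosite mapping


@dataclass
class GlycositeMap:
    """Per-residue PSM coverage and per-sequon glycosylation status."""

    accession: str
    length: int
    coverage: np.ndarray  # PSM count covering each residue (1-based -> idx 0)
    glyco_coverage: np.ndarray
    sequons: list[int]
    status: dict[int, str]  # sequon position -> confirmed|unconfirmed|not assessed

    @property
    def confirmed_sites(self) -> list[int]:
        return [s for s in self.sequons if self.status[s] == "confirmed"]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "residue": np.arange(1, self.length + 1),
                "psm_coverage": self.coverage,
                "glycopsm_coverage": self.glyco_coverage,
            }
        )
        frame["status"] = ""
        for pos, status in self.status.items():
            frame.loc[pos - 1, "status"] = status
        return frame


def glycosite_map(
    psms: Sequence[PSM], protein: Protein, glyco_deltas: Sequence[float] = (),
    delta_tol: float = 0.05,
) -> GlycositeMap:
    """Map PSM coverage and sequon status along one protein.

    ``glyco_deltas`` are the validated glycan masses; a sequon is confirmed
    by at least one localized glycoPSM at that position, unconfirmed when
    covered only by PSMs that never carry the glycan there, and not assessed
    when no PSM covers it.
    """
    length = len(protein.sequence)
    coverage = np.zeros(length, dtype=np.int64)
    glyco_coverage = np.zeros(length, dtype=np.int64)
    confirmed: set[int] = set()
    is_glyco_delta = lambda d: any(abs(d - g) <= delta_tol for g in glyco_deltas)

    for p in psms:
        if p.peptide.accession != protein.accession:
            continue
        coverage[p.peptide.start - 1 : p.peptide.end] += 1
        if p.delta and is_glyco_delta(p.delta):
            glyco_coverage[p.peptide.start - 1 : p.peptide.end] += 1
            if p.site:
                confirmed.add(p.protein_site)

    sequons = find_sequons(protein.sequence)
    status = {}
    for pos in sequons:
        if pos in confirmed:
            status[pos] = "confirmed"
        elif coverage[pos - 1] > 0:
            status[pos] = "unconfirmed"
        else:
            status[pos] = "not assessed"
    return GlycositeMap(protein.accession, length, coverage, glyco_coverage,
                        sequons, status)


# ---------------------------------------------------------------------------
# Quantification


@dataclass(frozen=True)
class QuantRecord:
    accession: str
    condition: str
    spectral_count: int
    length: int
    nsaf: float
    glyco_psm_count: int = 0


def nsaf(
    spectral_counts: Mapping[str, int],
    lengths: Mapping[str, int],
    condition: str = "",
    scale: float = 1.0,
    glyco_counts: Mapping[str, int] | None = None,
) -> list[QuantRecord]:
    """Normalized spectral abundance factors for one condition.

    SAF_i = SpC_i / L_i; NSAF_i = SAF_i / sum_j SAF_j, optionally multiplied
    by a report-scale factor. Unscaled NSAF values sum to 1.
    """
    glyco_counts = glyco_counts or {}
    saf = {}
    for acc, spc in spectral_counts.items():
        length = lengths[acc]
        if length <= 0:
            raise ValueError(f"non-positive length for {acc}")
        saf[acc] = spc / length
    total = sum(saf.values())
    if total <= 0:
        raise ValueError("total SAF is zero; nothing to normalize")
    return [
        QuantRecord(
            accession=acc,
            condition=condition,
            spectral_count=spectral_counts[acc],
            length=lengths[acc],
            nsaf=scale * s / total,
            glyco_psm_count=glyco_counts.get(acc, 0),
        )
        for acc, s in saf.items()
    ]


def nsaf_from_psms(
    psms: Sequence[PSM],
    proteins: Mapping[str, Protein],
    condition: str = "",
    scale: float = 1.0,
) -> list[QuantRecord]:
    counts: dict[str, int] = {}
    glyco: dict[str, int] = {}
    for p in psms:
        acc = p.peptide.accession
        counts[acc] = counts.get(acc, 0) + 1
        if p.delta:
            glyco[acc] = glyco.get(acc, 0) + 1
    lengths = {acc: len(proteins[acc].sequence) for acc in counts}
    return nsaf(counts, lengths, condition, scale, glyco)


def glycosylation_frequency(length: int, confirmed_sites: int) -> float | None:
    """Residues per confirmed glycosite: length / sites; None when no sites."""
    if length <= 0:
        raise ValueError("protein length must be positive")
    if confirmed_sites < 0:
        raise ValueError("confirmed site count cannot be negative")
    if confirmed_sites == 0:
        return None
    return length / confirmed_sites
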