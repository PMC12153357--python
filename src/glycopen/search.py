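"""Open (wildcard) and focused peptide-spectrum matching.

The open search matches each spectrum against a semi-N-ragged peptide index,
either directly (delta 0) or allowing an unknown delta mass within a
configured window on one asparagine residue; the delta is estimated
continuously as the precursor-mass discrepancy. The focused search restricts
candidate deltas to a fixed glycoform list and attempts site localization
from EThcD c/z ions. Confidence filtering is by target-decoy q-value with a
minimum matched-ion count.

Candidate generation uses a fragment-ion index: every indexed peptide's
naked b/y ladder is pooled into one sorted array so that, per spectrum, the
peptides sharing fragments with the peak list are found by binary search and
a single bincount, and only the best-supported candidates are fully scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import (
    DEFAULT_MODS,
    Peptide,
    Protein,
    digest,
    expand_modifications,
    make_decoys,
)
from .ions import by_ladder, cz_ladder, residue_masses
from .spectra import Spectrum


@dataclass(frozen=True)
class SearchParams:
    precursor_ppm: float = 10.0
    fragment_ppm_hcd: float = 10.0
    fragment_ppm_ethcd: float = 20.0
    wildcard_range: tuple[float, float] = (300.0, 2000.0)
    fdr_threshold: float = 0.01
    min_matched_ions: int = 4
    max_missed: int = 3
    specificity: str = "semi-N-ragged"
    max_variable_mods: int = 2
    min_length: int = 5
    max_length: int = 50
    #: Candidates fully scored per spectrum after fragment-index prefilter.
    prefilter_top: int = 8
    #: Minimum shared fragments for a wildcard candidate to enter scoring.
    prefilter_min_fragments: int = 2


@dataclass
class PSM:
    """A rank-1 peptide-spectrum match carrying a wildcard delta mass."""

    spectrum_id: str
    peptide: Peptide
    charge: int
    delta: float  # Da; 0.0 for an unmodified match
    site: int  # 1-based Asn position within the peptide; 0 = unlocalized
    score: float
    matched_by: int
    matched_cz: int
    q_value: float = math.nan
    precursor_neutral_mass: float = math.nan

    @property
    def decoy(self) -> bool:
        return self.peptide.decoy

    @property
    def matched_total(self) -> int:
        return self.matched_by + self.matched_cz

    @property
    def protein_site(self) -> int:
        """1-based modified-residue position on the protein (0 if unlocalized)."""
        return self.peptide.start + self.site - 1 if self.site else 0


def psms_to_frame(psms: Sequence[PSM]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spectrum_id": [p.spectrum_id for p in psms],
            "peptide": [p.peptide.sequence for p in psms],
            "accession": [p.peptide.accession for p in psms],
            "start": [p.peptide.start for p in psms],
            "end": [p.peptide.end for p in psms],
            "semi": [p.peptide.semi for p in psms],
            "charge": [p.charge for p in psms],
            "delta": [p.delta for p in psms],
            "site": [p.site for p in psms],
            "protein_site": [p.protein_site for p in psms],
            "score": [p.score for p in psms],
            "matched_by": [p.matched_by for p in psms],
            "matched_cz": [p.matched_cz for p in psms],
            "q_value": [p.q_value for p in psms],
            "decoy": [p.decoy for p in psms],
        }
    )


# ---------------------------------------------------------------------------
# Peptide index


class PeptideIndex:
    """Digested, modification-expanded peptides with a fragment-ion index."""

    def __init__(self, proteins: list[Protein], params: SearchParams,
                 with_decoys: bool = True):
        pool = list(proteins)
        if with_decoys:
            pool += make_decoys(proteins)
        self.peptides: list[Peptide] = []
        for prot in pool:
            for pep in digest(
                prot,
                max_missed=params.max_missed,
                specificity=params.specificity,
                min_length=params.min_length,
                max_length=params.max_length,
            ):
                self.peptides.extend(
                    expand_modifications(pep, DEFAULT_MODS, params.max_variable_mods)
                )
        self.masses = np.array([p.neutral_mass() for p in self.peptides])
        self.mass_order = np.argsort(self.masses, kind="stable")
        self.sorted_masses = self.masses[self.mass_order]
        self.has_asn = np.array(["N" in p.sequence for p in self.peptides])
        self._ladder_cache: dict[int, np.ndarray] = {}
        self._build_fragment_index()

    def _build_fragment_index(self) -> None:
        if not self.peptides:
            self.frag_mz = np.empty(0)
            self.frag_pid = np.empty(0, dtype=np.int32)
            return
        mz_chunks, id_chunks = [], []
        for i, pep in enumerate(self.peptides):
            b, y = by_ladder(residue_masses(pep))
            frags = np.concatenate([b, y])
            mz_chunks.append(frags)
            id_chunks.append(np.full(len(frags), i, dtype=np.int32))
        frag_mz = np.concatenate(mz_chunks)
        frag_pid = np.concatenate(id_chunks)
        order = np.argsort(frag_mz, kind="stable")
        self.frag_mz = frag_mz[order]
        self.frag_pid = frag_pid[order]

    def __len__(self) -> int:
        return len(self.peptides)

    def naked_ladder(self, idx: int) -> np.ndarray:
        """Concatenated naked b/y ladder of peptide ``idx`` (cached)."""
        arr = self._ladder_cache.get(idx)
        if arr is None:
            b, y = by_ladder(residue_masses(self.peptides[idx]))
            arr = self._ladder_cache[idx] = np.concatenate([b, y])
        return arr

    def ids_in_mass_window(self, lo: float, hi: float) -> np.ndarray:
        a = np.searchsorted(self.sorted_masses, lo, side="left")
        b = np.searchsorted(self.sorted_masses, hi, side="right")
        return self.mass_order[a:b]

    def fragment_support(self, spectrum: Spectrum, ppm: float) -> np.ndarray:
        """Per-peptide count of spectrum peaks shared with its b/y ladder."""
        counts = np.zeros(len(self.peptides), dtype=np.int32)
        mz = spectrum.mz
        tol = mz * ppm * 1e-6
        lo = np.searchsorted(self.frag_mz, mz - tol, side="left")
        hi = np.searchsorted(self.frag_mz, mz + tol, side="right")
        hits = [self.frag_pid[a:b] for a, b in zip(lo, hi) if b > a]
        if hits:
            ids, n = np.unique(np.concatenate(hits), return_counts=True)
            counts[ids] = n
        return counts


# ---------------------------------------------------------------------------
# Matching and scoring


def _match(mz_sorted: np.ndarray, values: np.ndarray, ppm: float) -> np.ndarray:
    """Boolean mask: which theoretical values have a peak within ppm."""
    if len(mz_sorted) == 0 or len(values) == 0:
        return np.zeros(len(values), dtype=bool)
    idx = np.searchsorted(mz_sorted, values)
    tol = values * ppm * 1e-6
    left = np.abs(mz_sorted[np.clip(idx - 1, 0, None)] - values) <= tol
    right = np.abs(mz_sorted[np.clip(idx, None, len(mz_sorted) - 1)] - values) <= tol
    return left | right


def _matched_intensity(spectrum: Spectrum, values: np.ndarray, ppm: float) -> float:
    """Summed intensity of the nearest peak for each matched theoretical ion."""
    if len(spectrum.mz) == 0 or len(values) == 0:
        return 0.0
    idx = np.searchsorted(spectrum.mz, values)
    left = np.clip(idx - 1, 0, None)
    right = np.clip(idx, None, len(spectrum.mz) - 1)
    d_left = np.abs(spectrum.mz[left] - values)
    d_right = np.abs(spectrum.mz[right] - values)
    nearest = np.where(d_left <= d_right, left, right)
    ok = np.abs(spectrum.mz[nearest] - values) <= values * ppm * 1e-6
    return float(spectrum.intensity[nearest[ok]].sum())


def _localize_cz(
    spectrum: Spectrum, peptide: Peptide, delta: float, ppm: float
) -> tuple[int, int]:
    """Best Asn site for a delta from c/z ions: (site or 0, matched count).

    The site is assigned only when a unique Asn position maximises the
    matched c/z count and at least one matched ion actually carries the
    delta (i.e. brackets the site); otherwise the match is kept unlocalized.
    """
    seq = peptide.sequence
    n = len(seq)
    asn = [i + 1 for i, aa in enumerate(seq) if aa == "N"]
    if not asn:
        return 0, 0
    best: list[tuple[int, int, int]] = []  # (total, shifted, site)
    for pos in asn:
        c, z = cz_ladder(residue_masses(peptide, site_delta=(pos, delta)))
        cm = _match(spectrum.mz, c, ppm)
        zm = _match(spectrum.mz, z, ppm)
        # c_i carries the delta iff i >= pos; z_i iff it spans residue pos,
        # i.e. i >= n - pos + 1 (z ions ordered z1..z(n-1)).
        shifted = int(cm[pos - 1:].sum() + zm[n - pos:].sum())
        best.append((int(cm.sum() + zm.sum()), shifted, pos))
    best.sort(key=lambda t: (-t[0], t[2]))
    total, shifted, site = best[0]
    unique = len(best) == 1 or best[0][0] > best[1][0]
    if total > 0 and shifted > 0 and unique:
        return site, total
    return 0, total


def score_psm(
    spectrum: Spectrum,
    peptide: Peptide,
    params: SearchParams,
    delta: float = 0.0,
) -> tuple[float, int, int, int]:
    """Hyperscore a candidate: (score, matched b/y, matched c/z, site).

    The score is ln(1 + summed matched intensity) plus log-factorials of the
    matched b/y and c/z ion counts; it is 0 when nothing matches and is
    invariant to peak order. For delta-carrying candidates the c/z ladder is
    evaluated with the delta parked on the best-supported Asn.
    """
    masses = residue_masses(peptide)
    b, y = by_ladder(masses)
    nb = int(_match(spectrum.mz, b, params.fragment_ppm_hcd).sum())
    ny = int(_match(spectrum.mz, y, params.fragment_ppm_hcd).sum())
    intensity = _matched_intensity(
        spectrum, np.concatenate([b, y]), params.fragment_ppm_hcd
    )
    site, ncz = 0, 0
    if delta:
        site, ncz = _localize_cz(spectrum, peptide, delta, params.fragment_ppm_ethcd)
        if ncz:
            ref = site if site else (peptide.sequence.index("N") + 1)
            c, z = cz_ladder(residue_masses(peptide, site_delta=(ref, delta)))
            cz = np.concatenate([c, z])
            matched_cz = cz[_match(spectrum.mz, cz, params.fragment_ppm_ethcd)]
            intensity += _matched_intensity(spectrum, matched_cz, params.fragment_ppm_ethcd)
    if nb + ny + ncz == 0:
        return 0.0, 0, 0, 0
    score = (
        math.log1p(intensity)
        + math.lgamma(nb + 1)
        + math.lgamma(ny + 1)
        + math.lgamma(ncz + 1)
    )
    return score, nb + ny, ncz, site


# ---------------------------------------------------------------------------
# Search drivers


def _best_psm(
    spectrum: Spectrum,
    index: PeptideIndex,
    candidates: list[tuple[int, float]],
    params: SearchParams,
) -> PSM | None:
    """Fully score (peptide id, delta) candidates; keep the rank-1 match."""
    scored = []
    for pid, delta in candidates:
        pep = index.peptides[pid]
        score, nby, ncz, site = score_psm(spectrum, pep, params, delta)
        if score <= 0.0:
            continue
        scored.append((score, nby + ncz, pep.sequence, pid, delta, site, nby, ncz))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    score, _, _, pid, delta, site, nby, ncz = scored[0]
    pep = index.peptides[pid]
    return PSM(
        spectrum_id=spectrum.spectrum_id,
        peptide=pep,
        charge=spectrum.charge,
        delta=delta,
        site=site,
        score=score,
        matched_by=nby,
        matched_cz=ncz,
        precursor_neutral_mass=spectrum.precursor_neutral_mass,
    )


def open_search(
    spectra: list[Spectrum], index: PeptideIndex, params: SearchParams | None = None
) -> list[PSM]:
    """Wildcard search: delta 0 or an unknown delta on one Asn per peptide.

    For each spectrum the rank-1 PSM is kept. Wildcard deltas are estimated
    as precursor neutral mass minus theoretical peptide mass and must fall
    inside ``params.wildcard_range``; candidate peptides must contain Asn.
    """
    params = params or SearchParams()
    if len(index) == 0:
        return []
    wc_lo, wc_hi = params.wildcard_range
    psms = []
    for spectrum in spectra:
        m = spectrum.precursor_neutral_mass
        tol = m * params.precursor_ppm * 1e-6
        candidates: list[tuple[int, float]] = [
            (int(pid), 0.0) for pid in index.ids_in_mass_window(m - tol, m + tol)
        ]
        wc_ids = index.ids_in_mass_window(m - wc_hi, m - wc_lo)
        wc_ids = wc_ids[index.has_asn[wc_ids]]
        if len(wc_ids) > params.prefilter_top:
            support = index.fragment_support(spectrum, params.fragment_ppm_hcd)
            sup = support[wc_ids]
            keep = sup >= params.prefilter_min_fragments
            wc_ids, sup = wc_ids[keep], sup[keep]
            if len(wc_ids) > params.prefilter_top:
                top = np.argpartition(-sup, params.prefilter_top)[: params.prefilter_top]
                wc_ids = wc_ids[top]
        candidates += [(int(pid), m - index.masses[pid]) for pid in wc_ids]
        psm = _best_psm(spectrum, index, candidates, params)
        if psm is not None:
            psms.append(psm)
    return psms


def focused_search(
    spectra: list[Spectrum],
    index: PeptideIndex,
    glycoform_masses: Sequence[float],
    params: SearchParams | None = None,
) -> list[PSM]:
    """Search with candidate deltas restricted to a fixed glycoform list.

    As :func:`open_search` but each non-zero delta must equal one of the
    given glycoform masses (the precursor must match peptide + glycoform
    within the precursor tolerance); site localization from c/z ions.
    """
    params = params or SearchParams()
    if len(index) == 0:
        return []
    psms = []
    for spectrum in spectra:
        m = spectrum.precursor_neutral_mass
        tol = m * params.precursor_ppm * 1e-6
        candidates: list[tuple[int, float]] = [
            (int(pid), 0.0) for pid in index.ids_in_mass_window(m - tol, m + tol)
        ]
        for g in glycoform_masses:
            ids = index.ids_in_mass_window(m - g - tol, m - g + tol)
            ids = ids[index.has_asn[ids]]
            candidates += [(int(pid), float(g)) for pid in ids]
        psm = _best_psm(spectrum, index, candidates, params)
        if psm is not None:
            psms.append(psm)
    return psms


# ---------------------------------------------------------------------------
# Target-decoy FDR


def estimate_fdr(psms: Sequence[PSM]) -> list[PSM]:
    """Assign target-decoy q-values.

    PSMs are sorted by score descending; the running FDR at each rank is
    (cumulative decoys) / (cumulative targets) and the q-value is the
    cumulative minimum taken from the bottom of the list, so q-values are
    non-decreasing with rank. Returns a new score-sorted list.
    """
    ranked = sorted(psms, key=lambda p: (-p.score, -p.matched_total, p.peptide.sequence))
    decoys = np.cumsum([p.decoy for p in ranked])
    targets = np.cumsum([not p.decoy for p in ranked])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(targets > 0, decoys / np.maximum(targets, 1), np.inf)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return [replace_q(p, float(qv)) for p, qv in zip(ranked, q)]


def replace_q(psm: PSM, q: float) -> PSM:
    out = replace(psm) if isinstance(psm, PSM) else psm
    out.q_value = q
    return out


def filter_psms(psms: Sequence[PSM], params: SearchParams | None = None) -> list[PSM]:
    """Confident target PSMs: q-value and matched-ion thresholds applied."""
    params = params or SearchParams()
    with_q = estimate_fdr(psms)
    return [
        p
        for p in with_q
        if not p.decoy
        and p.q_value <= params.fdr_threshold
        and p.matched_total >= params.min_matched_ions
    ]
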