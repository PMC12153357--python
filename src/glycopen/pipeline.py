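"""End-to-end glycoproteomic inference: the full discovery pipeline.

Chains the individual stages the way they are meant to be run on a dataset
with unknown glycans: wildcard open search, delta-mass histogram and
predominant-mass calling, focused re-search at the called masses, the
three-criterion glycan validation, glycosite mapping on the glycoprotein,
NSAF quantification, and the glycosylation-frequency summary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digest import Protein
from .histogram import DeltaHistogram, build_histogram, deltas_of, predominant_masses
from .search import PSM, PeptideIndex, SearchParams, filter_psms, focused_search, open_search
from .spectra import Spectrum
from .validate import (
    GlycositeMap,
    QuantRecord,
    ValidationParams,
    ValidationVerdict,
    glycosite_map,
    glycosylation_frequency,
    nsaf_from_psms,
    validate_modification,
)


@dataclass
class PipelineResult:
    open_psms: list[PSM]
    histogram: DeltaHistogram
    predominant: list[tuple[float, int]]
    focused_psms: list[PSM]
    verdicts: dict[float, ValidationVerdict]
    bona_fide_masses: list[float]
    site_maps: dict[str, GlycositeMap]
    quant: list[QuantRecord]
    frequency: dict[str, float | None]


def run_pipeline(
    proteins: list[Protein],
    spectra: list[Spectrum],
    params: SearchParams | None = None,
    validation: ValidationParams | None = None,
    top_k: int = 2,
    condition: str = "",
    index: PeptideIndex | None = None,
) -> PipelineResult:
    """Run discovery end to end on a proteome and its MS/MS spectra.

    Returns every intermediate stage so that callers can inspect the
    histogram, the per-mass verdicts and the site maps, not only the final
    quantities. ``index`` may be passed to reuse a prebuilt peptide index.
    """
    params = params or SearchParams()
    validation = validation or ValidationParams()
    index = index or PeptideIndex(proteins, params)
    by_id = {s.spectrum_id: s for s in spectra}
    by_acc = {p.accession: p for p in proteins}

    open_psms = filter_psms(open_search(spectra, index, params), params)
    hist = build_histogram(deltas_of(open_psms))
    calls = predominant_masses(hist, top_k=top_k)

    masses = [m for m, _ in calls]
    focused = filter_psms(focused_search(spectra, index, masses, params), params)

    verdicts: dict[float, ValidationVerdict] = {}
    for mass in masses:
        support = [p for p in focused if p.delta and abs(p.delta - mass) <= 0.05]
        verdicts[mass] = validate_modification(mass, support, by_id, by_acc, validation)
    bona_fide = [m for m, v in verdicts.items() if v.bona_fide]

    # Map sites and quantify on proteins that carry validated glycoPSMs,
    # using the focused PSM set (plain PSMs contribute coverage and counts).
    glyco_accessions = sorted(
        {
            p.peptide.accession
            for p in focused
            if p.delta and any(abs(p.delta - m) <= 0.05 for m in bona_fide)
        }
    )
    site_maps = {
        acc: glycosite_map(focused, by_acc[acc], bona_fide)
        for acc in glyco_accessions
    }
    quant = nsaf_from_psms(focused, by_acc, condition=condition)
    frequency = {
        acc: glycosylation_frequency(len(by_acc[acc].sequence),
                                     len(site_maps[acc].confirmed_sites))
        for acc in glyco_accessions
    }
    return PipelineResult(
        open_psms=open_psms,
        histogram=hist,
        predominant=calls,
        focused_psms=focused,
        verdicts=verdicts,
        bona_fide_masses=bona_fide,
        site_maps=site_maps,
        quant=quant,
        frequency=frequency,
    )
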