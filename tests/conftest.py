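"""Shared scenario fixtures.

Search-level tests run against a scaled-down synthetic dataset (a few
hundred spectra, a handful of background proteins) so the whole suite stays
fast; the full reference scenario is exercised in the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from glycopen.search import PeptideIndex, SearchParams, open_search
from glycopen.simulate import SimConfig, simulate_proteome, simulate_spectra


@dataclass
class Scenario:
    config: SimConfig
    proteins: list
    manifest: dict
    spectra: list
    truths: list
    index: PeptideIndex
    params: SearchParams

    @property
    def truth_by_id(self) -> dict:
        return {t.spectrum_id: t for t in self.truths}


def _build(config: SimConfig) -> Scenario:
    proteins, manifest = simulate_proteome(config)
    spectra, truths = simulate_spectra(proteins, manifest, config)
    params = SearchParams()
    return Scenario(config, proteins, manifest, spectra, truths,
                    PeptideIndex(proteins, params), params)


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """Default-style conditions at reduced scale (noise, mass error, decoys)."""
    return _build(
        SimConfig(seed=7, n_background_proteins=4, background_length=(150, 250),
                  n_spectra=300)
    )


@pytest.fixture(scope="session")
def noiseless_scenario() -> Scenario:
    """Complete ladders, no noise peaks, no mass error."""
    return _build(
        SimConfig(seed=11, n_background_proteins=4, background_length=(150, 250),
                  n_spectra=200, ladder_completeness=1.0, noise_peaks=0,
                  precursor_ppm_sd=0.0, fragment_ppm_sd=0.0)
    )


@pytest.fixture(scope="session")
def small_open_psms(small_scenario) -> list:
    return open_search(small_scenario.spectra, small_scenario.index,
                       small_scenario.params)
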