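"""Open/focused search: scoring, wildcard deltas, localization, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopen.digest import Peptide
from glycopen.search import (
    PSM,
    SearchParams,
    estimate_fdr,
    filter_psms,
    focused_search,
    open_search,
    score_psm,
)
from glycopen.simulate import GLYCAN_NAME

PARAMS = SearchParams()


def _peptide(seq: str) -> Peptide:
    return Peptide(seq, "P", 1, len(seq), 0)


class TestScoring:
    def test_empty_spectrum_scores_zero(self):
        from glycopen.spectra import Spectrum

        empty = Spectrum("s", 500.0, 2, np.array([]), np.array([]))
        score, nby, ncz, site = score_psm(empty, _peptide("TESTLK"), PARAMS)
        assert score == 0.0 and nby == 0 and ncz == 0 and site == 0

    def test_score_deterministic_and_peak_order_invariant(self, noiseless_scenario):
        sc = noiseless_scenario
        spectrum = sc.spectra[0]
        truth = sc.truths[0]
        pep = _peptide(truth.peptide)
        first = score_psm(spectrum, pep, PARAMS, truth.mod_delta)
        again = score_psm(spectrum, pep, PARAMS, truth.mod_delta)
        assert first == again
        # shuffle peaks: Spectrum re-sorts, score must not change
        from glycopen.spectra import Spectrum

        rng = np.random.default_rng(0)
        order = rng.permutation(len(spectrum.mz))
        shuffled = Spectrum(spectrum.spectrum_id, spectrum.precursor_mz,
                            spectrum.charge, spectrum.mz[order],
                            spectrum.intensity[order])
        assert score_psm(shuffled, pep, PARAMS, truth.mod_delta) == first

    def test_true_peptide_outscores_random_same_length(self, noiseless_scenario):
        """The generating peptide wins against 50 random decoy sequences."""
        sc = noiseless_scenario
        rng = np.random.default_rng(42)
        alphabet = np.array(list("ADEFGHILMNPQSTVWY"))
        wins = trials = 0
        for spectrum, truth in list(zip(sc.spectra, sc.truths))[:40]:
            if truth.mod_name:
                continue
            true_score = score_psm(spectrum, _peptide(truth.peptide), PARAMS)[0]
            n = len(truth.peptide)
            beaten = sum(
                true_score > score_psm(
                    spectrum,
                    _peptide("".join(rng.choice(alphabet, n - 1)) + truth.peptide[-1]),
                    PARAMS,
                )[0]
                for _ in range(50)
            )
            trials += 1
            wins += beaten == 50
        assert trials >= 10
        assert wins / trials >= 0.95


class TestOpenSearch:
    def test_empty_index_gives_empty_result(self, small_scenario):
        from glycopen.search import PeptideIndex

        empty = PeptideIndex([], small_scenario.params)
        assert open_search(small_scenario.spectra[:5], empty) == []

    def test_recovers_peptides_and_deltas_on_noiseless_data(self, noiseless_scenario):
        sc = noiseless_scenario
        psms = {p.spectrum_id: p for p in open_search(sc.spectra, sc.index, sc.params)}
        glyco_hits = 0
        for truth in sc.truths:
            psm = psms[truth.spectrum_id]
            assert psm.peptide.sequence == truth.peptide
            if truth.mod_name == GLYCAN_NAME:
                # delta within 10 ppm of the true glycan mass
                assert abs(psm.delta - truth.mod_delta) / truth.mod_delta < 1e-5
                glyco_hits += 1
            elif truth.mod_name is None:
                assert psm.delta == 0.0
        assert glyco_hits > 0

    def test_delta_outside_wildcard_window_not_reported(self, noiseless_scenario):
        """A 250 Da shift is below the 300-2000 window: no wildcard PSM."""
        from glycopen.simulate import SimConfig, _make_spectrum

        sc = noiseless_scenario
        rng = np.random.default_rng(0)
        config = SimConfig(seed=0, noise_peaks=0, ladder_completeness=1.0,
                           precursor_ppm_sd=0.0, fragment_ppm_sd=0.0)
        truth = next(t for t in sc.truths if t.mod_name == GLYCAN_NAME)
        pep = next(
            p for p in sc.index.peptides
            if p.sequence == truth.peptide and not p.mods and not p.decoy
        )
        spectrum = _make_spectrum(rng, config, "offwindow", pep, 2,
                                  mod_delta=250.0, mod_site=truth.mod_site)
        psms = open_search([spectrum], sc.index, sc.params)
        assert all(not (0 < p.delta) or p.peptide.sequence != pep.sequence
                   for p in psms)

    def test_unmodified_spectrum_gets_delta_zero(self, noiseless_scenario):
        sc = noiseless_scenario
        plain = [t for t in sc.truths if t.mod_name is None][:10]
        by_id = {t.spectrum_id: t for t in plain}
        subset = [s for s in sc.spectra if s.spectrum_id in by_id]
        for psm in open_search(subset, sc.index, sc.params):
            assert psm.delta == 0.0


class TestFocusedSearch:
    def test_reported_deltas_restricted_to_glycoform_list(self, small_scenario):
        sc = small_scenario
        glycoforms = [1650.64, 631.26]
        psms = focused_search(sc.spectra, sc.index, glycoforms, sc.params)
        for psm in psms:
            assert psm.delta == 0.0 or psm.delta in glycoforms

    def test_empty_glycoform_list_gives_only_delta_zero(self, small_scenario):
        sc = small_scenario
        for psm in focused_search(sc.spectra[:40], sc.index, [], sc.params):
            assert psm.delta == 0.0

    def test_complete_ladders_localize_true_site(self, noiseless_scenario):
        sc = noiseless_scenario
        psms = focused_search(sc.spectra, sc.index, [sc.config.glycan_delta],
                              sc.params)
        truth_by_id = sc.truth_by_id
        localized = checked = 0
        for psm in psms:
            truth = truth_by_id[psm.spectrum_id]
            if truth.mod_name != GLYCAN_NAME:
                continue
            checked += 1
            if psm.site:
                localized += 1
                assert psm.site == truth.mod_site
        assert checked > 0
        assert localized / checked >= 0.95


def brute_force_qvalues(flags):
    """Oracle: running decoy/target FDR then cumulative minimum from below."""
    fdrs = []
    d = t = 0
    for decoy in flags:
        d += decoy
        t += not decoy
        fdrs.append(d / t if t else float("inf"))
    out = fdrs[:]
    for i in range(len(out) - 2, -1, -1):
        out[i] = min(out[i], out[i + 1])
    return out


def _psm(score, decoy, name="PEPTIDEK"):
    pep = Peptide(name, "rev_P" if decoy else "P", 1, len(name), 0, decoy=decoy)
    return PSM("s", pep, 2, 0.0, 0, score, 4, 0)


class TestFdr:
    def test_all_targets_q_zero(self):
        psms = [_psm(10.0 - i, False) for i in range(5)]
        assert all(p.q_value == 0.0 for p in estimate_fdr(psms))

    def test_interleaved_scores_approach_one(self):
        """Alternating target/decoy 1:1: q at the tail tends towards 1."""
        psms = [_psm(10.0 - i, decoy=bool(i % 2)) for i in range(10)]
        annotated = estimate_fdr(psms)
        qs = [p.q_value for p in annotated]
        # hand computation: running FDR [0,1,1/2,1,2/3,1,3/4,1,4/5,1],
        # cumulative minimum from the bottom
        assert qs == pytest.approx([0, 1/2, 1/2, 2/3, 2/3, 3/4, 3/4, 4/5, 4/5, 1])

    @given(st.lists(st.tuples(st.floats(0, 100, allow_nan=False), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_oracle(self, entries):
        psms = [_psm(score, decoy, name=f"PEP{i}K")
                for i, (score, decoy) in enumerate(entries)]
        annotated = estimate_fdr(psms)
        oracle = brute_force_qvalues([p.decoy for p in annotated])
        assert [p.q_value for p in annotated] == pytest.approx(oracle)

    @given(st.lists(st.tuples(st.floats(0, 100, allow_nan=False), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_qvalues_non_decreasing_with_rank(self, entries):
        psms = [_psm(score, decoy, name=f"PEP{i}K")
                for i, (score, decoy) in enumerate(entries)]
        qs = [p.q_value for p in estimate_fdr(psms)]
        assert qs == sorted(qs)

    def test_filter_drops_decoys_and_low_support(self, small_scenario, small_open_psms):
        kept = filter_psms(small_open_psms, small_scenario.params)
        assert kept, "no confident PSMs survived filtering"
        for psm in kept:
            assert not psm.decoy
            assert psm.q_value <= small_scenario.params.fdr_threshold
            assert psm.matched_total >= small_scenario.params.min_matched_ions
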