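"""Candidate indexing, spectrum scoring, and target-decoy FDR."""

import itertools

import numpy as np
import pytest

from lipopept.chem import Peptidoform, mz, peptide_neutral_mass, registry_lookup
from lipopept.digestion import DigestParams, VariableModSpec, digest, enumerate_peptidoforms
from lipopept.fragments import default_rules
from lipopept.search import (
    PSM,
    SearchParams,
    build_index,
    compute_fdr,
    reverse_decoy,
    run_search,
    search_spectrum,
)
from lipopept.simulate import SpectrumSimParams, simulate_spectrum
from lipopept.spectra import Spectrum

TOY_PROTEINS = [
    ("P1", "MKAACGLDERVVCAAGHKLLDPEWKR"),
    ("P2", "MGGCALDDKAAVNQECPLRGGAWK"),
]


def toy_params(**overrides):
    defaults = dict(
        digest=DigestParams(missed_cleavages=1, min_length=5, max_length=50),
        mods=VariableModSpec((registry_lookup("palmitoyl"),), 2),
    )
    defaults.update(overrides)
    return SearchParams(**defaults)


class TestBuildIndex:
    def test_size_matches_brute_force(self):
        params = toy_params()
        index = build_index(None, params, proteins=TOY_PROTEINS)
        expected = 0
        for _acc, sequence in TOY_PROTEINS:
            for seq in (sequence, reverse_decoy(sequence)):
                peptides = {p.sequence for p in digest(seq, params.digest)}
                for pep in peptides:
                    expected += len(enumerate_peptidoforms(pep, params.mods))
        assert len(index) == expected

    def test_masses_sorted(self):
        index = build_index(None, toy_params(), proteins=TOY_PROTEINS)
        assert np.all(np.diff(index.masses) >= 0)

    def test_decoys_disjoint_from_targets(self):
        index = build_index(None, toy_params(), proteins=TOY_PROTEINS)
        targets = {str(f) for f, d in zip(index.peptidoforms, index.is_decoy) if not d}
        decoys = {str(f) for f, d in zip(index.peptidoforms, index.is_decoy) if d}
        assert targets.isdisjoint(decoys)

    def test_decoy_preserves_tryptic_cterm(self):
        assert reverse_decoy("AACGLDER") == "EDLGCAAR"

    def test_length_filter(self):
        narrow = toy_params(digest=DigestParams(
            missed_cleavages=1, min_length=7, max_length=50))
        wide = toy_params(digest=DigestParams(
            missed_cleavages=1, min_length=1, max_length=50))
        index_narrow = build_index(None, narrow, proteins=TOY_PROTEINS)
        index_wide = build_index(None, wide, proteins=TOY_PROTEINS)
        assert all(len(f.sequence) >= 7 for f in index_narrow.peptidoforms)
        assert len(index_wide) > len(index_narrow)


class TestSearchSpectrum:
    def _planted(self, seed=0):
        palmitoyl = registry_lookup("palmitoyl")
        form = Peptidoform("AACGLDER", ((3, palmitoyl),))
        spectrum, _ = simulate_spectrum(SpectrumSimParams(
            peptidoform=form, precursor_charge=2, seed=seed))
        return form, spectrum

    def test_planted_peptidoform_ranks_first(self):
        form, spectrum = self._planted()
        params = toy_params()
        index = build_index(None, params, proteins=TOY_PROTEINS)
        hits = search_spectrum(spectrum, index, params, max_rank=5)
        assert hits and str(hits[0].peptidoform) == str(form)
        assert not hits[0].is_decoy

    def test_precursor_off_by_50ppm_yields_nothing(self):
        _form, spectrum = self._planted()
        spectrum.precursor_mz *= 1 + 50e-6
        params = toy_params()
        index = build_index(None, params, proteins=TOY_PROTEINS)
        assert search_spectrum(spectrum, index, params) == []

    def test_isobaric_acyl_swap_ranked_by_site_ions(self):
        palmitoyl = registry_lookup("palmitoyl")
        stearoyl = registry_lookup("stearoyl")
        peptide = "GGCALDDKAAVNQECPLR"
        true = Peptidoform(peptide, ((3, palmitoyl), (15, stearoyl)))
        swapped = Peptidoform(peptide, ((3, stearoyl), (15, palmitoyl)))
        assert peptide_neutral_mass(true) == pytest.approx(
            peptide_neutral_mass(swapped), abs=1e-9)
        spectrum, _ = simulate_spectrum(SpectrumSimParams(
            peptidoform=true, precursor_charge=2, seed=3))
        params = toy_params(mods=VariableModSpec((palmitoyl, stearoyl), 2))
        index = build_index(None, params, proteins=TOY_PROTEINS)
        hits = search_spectrum(spectrum, index, params, max_rank=0)
        scored = {str(h.peptidoform): h.score for h in hits}
        assert str(true) in scored and str(swapped) in scored
        assert scored[str(true)] > scored[str(swapped)]

    def test_unknown_charge_assumed(self):
        form, spectrum = self._planted()
        spectrum.precursor_charge = None
        params = toy_params()
        index = build_index(None, params, proteins=TOY_PROTEINS)
        hits = search_spectrum(spectrum, index, params)
        assert hits and hits[0].charge_assumed and hits[0].charge == 2


class TestComputeFdr:
    def _psm(self, score, is_decoy):
        return PSM("s", Peptidoform("AAAAK"), 2, score, is_decoy, "P", 0.0)

    def test_hand_computed_four_psms(self):
        psms = [self._psm(10, False), self._psm(9, False),
                self._psm(8, True), self._psm(7, False)]
        out = compute_fdr(psms)
        # running FDR: 0/1, 0/2, 1/2, 1/3 -> monotone minimum from the bottom
        assert [p.q_value for p in out] == pytest.approx([0.0, 0.0, 1 / 3, 1 / 3])

    def test_all_decoys_on_top(self):
        psms = [self._psm(10, True), self._psm(9, True), self._psm(1, False)]
        out = compute_fdr(psms)
        assert all(p.q_value == 1.0 for p in out)

    def test_no_decoys(self):
        out = compute_fdr([self._psm(s, False) for s in (5, 4, 3)])
        assert all(p.q_value == 0.0 for p in out)

    def test_zero_targets(self):
        out = compute_fdr([self._psm(5, True)])
        assert out[0].q_value == 1.0

    def test_q_nonincreasing_with_score(self):
        rng = np.random.default_rng(8)
        psms = [self._psm(float(s), bool(rng.random() < 0.4))
                for s in rng.uniform(0, 20, 100)]
        out = compute_fdr(psms)
        qs = [p.q_value for p in out]  # sorted by descending score
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
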