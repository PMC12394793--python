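"""Peak matching, ion coverage, and modification-site localization."""

import numpy as np
import pytest

from lipopept.annotation import (
    annotate,
    candidate_assignments,
    ion_coverage,
    localize,
    match_peaks,
)
from lipopept.chem import Peptidoform, registry_lookup
from lipopept.fragments import FragmentIon, default_rules, generate_fragments
from lipopept.simulate import SpectrumSimParams, simulate_spectrum
from lipopept.spectra import Spectrum


def theo(mz_value, series="y", index=1, charge=1, label=None):
    return FragmentIon(series, index, charge, mz_value,
                       label=label or f"{series}{index}")


def spectrum_from(mzs, intensities=None, scan_id="s"):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.ones_like(mzs)
    return Spectrum(scan_id, mzs, intensities, ms_level=2,
                    precursor_mz=500.0, precursor_charge=2)


class TestMatchPeaks:
    def test_ppm_error_sign_and_value(self):
        matches = match_peaks(spectrum_from([500.0050]), [theo(500.0)], 20)
        assert len(matches) == 1
        assert matches[0].ppm_error == pytest.approx(10.0, abs=1e-6)

    def test_outside_tolerance(self):
        assert match_peaks(spectrum_from([500.0150]), [theo(500.0)], 20) == []

    def test_nearest_peak_wins(self):
        # +5 ppm and -8 ppm candidates: the +5 ppm peak is closer
        s = spectrum_from([500.0 * (1 - 8e-6), 500.0 * (1 + 5e-6)])
        matches = match_peaks(s, [theo(500.0)], 20)
        assert matches[0].ppm_error == pytest.approx(5.0, abs=1e-6)

    def test_shared_peak_flagged(self):
        s = spectrum_from([500.0])
        matches = match_peaks(s, [theo(500.0, "y", 1), theo(500.0005, "b", 2)], 20)
        assert len(matches) == 2 and all(m.shared for m in matches)

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(9)
        s = spectrum_from(np.sort(rng.uniform(100, 1500, 200)))
        ions = [theo(m) for m in rng.uniform(100, 1500, 50)]
        small = {(m.fragment.mz, m.observed_mz) for m in match_peaks(s, ions, 5)}
        large = {(m.fragment.mz, m.observed_mz) for m in match_peaks(s, ions, 50)}
        assert small <= large


class TestIonCoverage:
    def _match(self, series, index, losses=()):
        ion = FragmentIon(series, index, 1, 500.0, losses=losses, label="x")
        from lipopept.annotation import PeakMatch
        return PeakMatch(ion, 500.0, 1.0, 0.0, 0)

    def test_full_y_ladder(self):
        matches = [self._match("y", i) for i in range(1, 8)]
        assert ion_coverage(matches, 8) == 1.0

    def test_no_matches(self):
        assert ion_coverage([], 8) == 0.0

    def test_partial_with_loss_ion(self, palmitoyl):
        matches = [
            self._match("y", 2, losses=(palmitoyl.delta_formula,)),
            self._match("b", 5),
        ]
        # y2 covers site 6, b5 covers site 5
        assert ion_coverage(matches, 8) == pytest.approx(2 / 7)

    def test_strict_mode_excludes_loss_ions(self, palmitoyl):
        matches = [self._match("y", 2, losses=(palmitoyl.delta_formula,))]
        assert ion_coverage(matches, 8, include_losses=False) == 0.0

    def test_precursor_and_diagnostic_never_count(self):
        from lipopept.annotation import PeakMatch
        matches = [
            PeakMatch(FragmentIon("p", 0, 2, 700.0, label="p^2+"), 700.0, 1.0, 0.0, 0),
            PeakMatch(FragmentIon("d", 0, 1, 239.2, label="d*"), 239.2, 1.0, 0.0, 1),
        ]
        assert ion_coverage(matches, 8) == 0.0

    def test_coverage_is_one_on_own_theoretical_spectrum(self, palmitoyl):
        form = Peptidoform("GCAVLDK", ((2, palmitoyl),))
        rules = default_rules("HCD")
        s, _ = simulate_spectrum(SpectrumSimParams(
            peptidoform=form, precursor_charge=2, seed=5))
        result = annotate(s, form, rules)
        assert result.ion_coverage == 1.0
        assert 0.0 <= result.matched_intensity_fraction <= 1.0


class TestLocalize:
    def test_acyl_swap_resolved(self, palmitoyl, stearoyl):
        peptide = "GCGACAGLK"
        true = Peptidoform(peptide, ((2, palmitoyl), (5, stearoyl)))
        s, _ = simulate_spectrum(SpectrumSimParams(
            peptidoform=true, precursor_charge=2, seed=1))
        result = localize(s, peptide, [palmitoyl, stearoyl], [2, 5],
                          default_rules("HCD"))
        assert str(result.best) == str(true)
        assert result.delta_score > 0
        assert result.site_determining_matches

    def test_uninformative_spectrum_is_ambiguous(self, palmitoyl):
        peptide = "GCGCGLK"
        # only the precursor is present: identical for both assignments
        form = Peptidoform(peptide, ((2, palmitoyl),))
        from lipopept.chem import mz, peptide_neutral_mass
        s = spectrum_from([mz(peptide_neutral_mass(form), 2)])
        s.precursor_mz = mz(peptide_neutral_mass(form), 2)
        result = localize(s, peptide, [palmitoyl], [2, 4], default_rules("HCD"))
        assert result.delta_score == 0.0 and result.ambiguous

    def test_single_candidate_rejected(self, palmitoyl):
        s = spectrum_from([500.0])
        with pytest.raises(ValueError, match="candidate"):
            localize(s, "GCGLK", [palmitoyl], [2], default_rules("HCD"))

    def test_assignment_enumeration(self, palmitoyl, stearoyl):
        forms = candidate_assignments("GCGCGCK", [palmitoyl, stearoyl], [2, 4, 6])
        assert len(forms) == 6  # ordered pairs of distinct sites

    def test_noiseless_recovery(self, peptidoform_factory, palmitoyl, stearoyl):
        """On noiseless simulated HCD spectra the true isoform ranks first."""
        rng = np.random.default_rng(77)
        mods = [palmitoyl, stearoyl, registry_lookup("myristoyl")]
        correct = total = 0
        alphabet = "AGLVFDENQHIPW"
        while total < 50:
            n = int(rng.integers(8, 13))
            residues = list(rng.choice(list(alphabet), size=n))
            sites = sorted(rng.choice(range(2, n - 1),
                                      size=int(rng.integers(2, 4)), replace=False))
            for site in sites:
                residues[site - 1] = "C"
            residues[-1] = "K"
            peptide = "".join(residues)
            k = int(rng.integers(1, len(sites)))
            chosen = [mods[int(rng.integers(len(mods)))] for _ in range(k)]
            placed = sorted(rng.choice(sites, size=k, replace=False))
            true = Peptidoform(peptide, tuple(zip(placed, chosen)))
            if len(candidate_assignments(peptide, chosen, sites)) < 2:
                continue
            s, _ = simulate_spectrum(SpectrumSimParams(
                peptidoform=true, precursor_charge=2,
                seed=int(rng.integers(2 ** 31))))
            result = localize(s, peptide, chosen, sites, default_rules("HCD"))
            total += 1
            correct += str(result.best) == str(true)
        assert correct == total
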