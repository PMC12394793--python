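"""Fragment generation: series arithmetic, neutral-loss channels, precursors."""

import numpy as np
import pytest

from lipopept.chem import (
    PROTON_MASS,
    Peptidoform,
    monoisotopic_mass,
    peptide_neutral_mass,
    registry_lookup,
)
from lipopept.fragments import (
    default_rules,
    generate_fragments,
    precursor_ions,
)
from .conftest import random_peptidoform


def ion_map(ions):
    return {ion.label: ion for ion in ions}


class TestDefaultRules:
    def test_collisional_series(self):
        for activation in ("CID", "HCD"):
            rules = default_rules(activation)
            assert {"b", "y"} <= set(rules.backbone_series)

    def test_etd_series(self):
        rules = default_rules("ETD")
        assert set(rules.backbone_series) == {"c", "zdot"}

    def test_hcd_has_y_acyl_loss_channel(self, palmitoyl):
        channels = default_rules("HCD").channels_for(palmitoyl)
        assert any("y" in ch.series and str(ch.formula) == "C16H30O"
                   for ch in channels)

    def test_cid_acyl_loss_skips_b_ions(self, palmitoyl):
        channels = default_rules("CID").channels_for(palmitoyl)
        acyl = [ch for ch in channels if str(ch.formula) == "C16H30O"]
        assert acyl and all("b" not in ch.series for ch in acyl)

    def test_etd_sidechain_loss_masses(self, palmitoyl):
        # S-C bond cleavage: acyl + sulfur radical, with/without H transfer
        channels = default_rules("ETD").channels_for(palmitoyl)
        masses = sorted(ch.formula.mass for ch in channels)
        assert masses[0] == pytest.approx(270.2017, abs=5e-4)
        assert masses[1] == pytest.approx(271.2096, abs=5e-4)
        assert all(ch.formula.radical for ch in channels)

    def test_unknown_activation(self):
        with pytest.raises(ValueError):
            default_rules("UVPD")


class TestBackboneArithmetic:
    def test_by_complementarity_identity(self):
        rng = np.random.default_rng(42)
        rules = default_rules("HCD")
        for _ in range(50):
            p = random_peptidoform(rng)
            if len(p) < 2:
                continue
            ions = {(i.series, i.index): i.mz for i in generate_fragments(
                p, rules, max_fragment_charge=1) if not i.losses and i.is_backbone}
            mass = peptide_neutral_mass(p)
            n = len(p)
            for i in range(1, n):
                total = ions[("b", i)] + ions[("y", n - i)] - 2 * PROTON_MASS
                assert total == pytest.approx(mass, abs=1e-6)

    def test_series_offsets(self):
        rng = np.random.default_rng(43)
        rules = default_rules("EThcD")
        for _ in range(20):
            p = random_peptidoform(rng, with_mod_probability=0.0)
            ions = {(i.series, i.index): i.mz for i in generate_fragments(
                p, rules, max_fragment_charge=1) if not i.losses and i.is_backbone}
            for i in range(1, len(p)):
                assert ions[("c", i)] - ions[("b", i)] == pytest.approx(
                    17.026549, abs=1e-6)
                assert ions[("y", i)] - ions[("zdot", i)] == pytest.approx(
                    16.018724, abs=1e-6)

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            generate_fragments(Peptidoform("G"), default_rules("HCD"))


class TestNeutralLosses:
    def test_y_star_offset(self, palmitoyl):
        p = Peptidoform("GLCAK", ((3, palmitoyl),))
        ions = ion_map(generate_fragments(p, default_rules("HCD"),
                                          max_fragment_charge=2))
        for i in (3, 4):  # y ions spanning Cys3
            for z in (1, 2):
                plain = ions[f"y{i}" if z == 1 else f"y{i}^{z}+"]
                star = ions[f"y{i}*" if z == 1 else f"y{i}*^{z}+"]
                assert plain.mz - star.mz == pytest.approx(238.2297 / z, abs=1e-4)

    def test_loss_exactness(self):
        rng = np.random.default_rng(44)
        for activation in ("CID", "HCD", "ETD"):
            rules = default_rules(activation)
            for _ in range(20):
                p = random_peptidoform(rng, with_mod_probability=1.0)
                ions = generate_fragments(p, rules, max_fragment_charge=2)
                plain = {(i.series, i.index, i.charge, i.water_delta): i.mz
                         for i in ions if not i.losses}
                for ion in ions:
                    if not ion.losses or ion.water_delta:
                        continue
                    key = (ion.series, ion.index, ion.charge, 0)
                    if key not in plain:
                        continue
                    loss = sum(f.mass for f in ion.losses)
                    assert plain[key] - ion.mz == pytest.approx(
                        loss / ion.charge, abs=1e-9)

    def test_no_loss_outside_modified_span(self, palmitoyl):
        # Cys at position 2: y1 and y2 exclude it, b3..b4 include it
        p = Peptidoform("GCAGK", ((2, palmitoyl),))
        ions = generate_fragments(p, default_rules("HCD"), max_fragment_charge=1)
        for ion in ions:
            if not ion.losses or not ion.is_backbone:
                continue
            if ion.series in ("b", "c"):
                assert ion.index >= 2
            else:
                assert ion.index >= 4  # y must reach back to Cys2

    def test_unmodified_peptide_has_no_loss_ions(self):
        ions = generate_fragments(Peptidoform("GAVLK"), default_rules("CID"),
                                  max_fragment_charge=1)
        assert all(not ion.losses for ion in ions)

    def test_double_loss_for_diacylated_span(self, palmitoyl, stearoyl):
        p = Peptidoform("GCGCGLK", ((2, palmitoyl), (4, stearoyl)))
        labels = {i.label for i in generate_fragments(
            p, default_rules("HCD"), max_fragment_charge=1)}
        assert "b5**" in labels  # span covers both acyl sites


class TestDiagnosticAndPrecursor:
    def test_palmitoyl_diagnostic_ion(self, palmitoyl):
        p = Peptidoform("ICLR", ((2, palmitoyl),))
        ions = ion_map(generate_fragments(p, default_rules("HCD")))
        assert ions["d*"].mz == pytest.approx(239.2369, abs=5e-4)

    def test_no_diagnostic_under_etd(self, palmitoyl):
        p = Peptidoform("ICLR", ((2, palmitoyl),))
        ions = generate_fragments(p, default_rules("ETD"))
        assert all(ion.series != "d" for ion in ions)

    def test_unmodified_precursor_set(self):
        ions = precursor_ions(Peptidoform("GAVLK"), 2, default_rules("HCD"))
        labels = {i.label for i in ions}
        assert labels == {"p", "p^2+", "p-H2O^2+", "p+H2O^2+"}

    def test_farnesyl_precursor_loss(self):
        farnesyl = registry_lookup("farnesyl")
        p = Peptidoform("GCVLK", ((2, farnesyl),))
        ions = precursor_ions(p, 2, default_rules("HCD"))
        losses = [sum(f.mass for f in i.losses) for i in ions if i.losses]
        assert any(loss == pytest.approx(204.1878, abs=5e-5) for loss in losses)

    def test_geranylgeranyl_partial_loss(self):
        gg = registry_lookup("geranylgeranyl")
        p = Peptidoform("GCVLK", ((2, gg),))
        ions = precursor_ions(p, 2, default_rules("HCD"))
        losses = [sum(f.mass for f in i.losses) for i in ions if i.losses]
        assert any(loss == pytest.approx(272.2504, abs=5e-5) for loss in losses)
        # partial fragmentation of the C20 isoprenoid sheds C10H16
        assert any(loss == pytest.approx(136.1252, abs=5e-5) for loss in losses)

    def test_etd_charge_reduced_precursors(self, palmitoyl):
        p = Peptidoform("ICLAK", ((2, palmitoyl),))
        neutral = peptide_neutral_mass(p)
        ions = precursor_ions(p, 3, default_rules("ETD"))
        reduced = [i for i in ions if "charge-reduced" in i.label]
        assert {i.charge for i in reduced} == {1, 2}
        for ion in reduced:
            # all three protons retained at reduced charge
            assert ion.mz == pytest.approx(
                (neutral + 3 * PROTON_MASS) / ion.charge, abs=1e-6)

    def test_asterisk_count_matches_losses(self, palmitoyl, stearoyl):
        p = Peptidoform("GCGCGLK", ((2, palmitoyl), (4, stearoyl)))
        for ion in generate_fragments(p, default_rules("HCD")):
            if ion.series == "d":
                continue  # the asterisk in d* is part of its canonical name
            assert ion.label.count("*") == len(ion.losses)
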