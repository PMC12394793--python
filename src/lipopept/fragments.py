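"""Theoretical fragment ions for lipidated peptides.

Long-chain S-acyl groups sit on cysteine via a labile thioester; prenyl
groups via a more loss-prone thioether.  Under collisional activation the
modification is shed as a neutral (the acyl ketene, e.g. C16H30O for
palmitoyl, or the intact isoprenoid C15H24/C20H32), producing *-ions:
precursor p*, fragment y*/b* companions, and a low-mass acylium-type
diagnostic ion d*.  Electron transfer dissociation leaves the thioester
intact but cleaves the cysteine S–C bond, losing the acyl chain plus sulfur
as a radical (C16H30OS˙ / C16H31OS˙ for palmitoyl).  This module encodes
those channels per activation type and emits the complete theoretical ion
list for a peptidoform.

Activation-specific defaults:

========  ===============  ==========================  =====================
method    backbone series  acyl (thioester) losses     prenyl (thioether)
========  ===============  ==========================  =====================
CID       b, y             y, p                        b, y, p
HCD       b, y             b, y, p                     b, y, p
ETD       c, z˙            S–C radical losses on p, z˙  —
EThcD     b, y, c, z˙      b, y, p + S–C on p, z˙      b, y, p
========  ===============  ==========================  =====================

A diagnostic d* ion (acyl delta + proton) is emitted under CID/HCD/EThcD;
geranylgeranyl precursors additionally shed a partial C10H16 fragment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence, TextIO

from .chem import (
    AMINO_ACID_MASSES,
    LABILITY_STABLE,
    LABILITY_THIOESTER,
    LABILITY_THIOETHER,
    N_TERM,
    C_TERM,
    PROTON_MASS,
    WATER,
    ChemicalFormula,
    Modification,
    Peptidoform,
    parse_formula,
    peptide_neutral_mass,
)

__all__ = [
    "ActivationRules",
    "FragmentIon",
    "LossChannel",
    "default_rules",
    "generate_fragments",
    "precursor_ions",
    "write_fragment_tsv",
    "ACTIVATIONS",
]

ACTIVATIONS = ("CID", "HCD", "ETD", "EThcD")

_NH3_MASS = parse_formula("NH3").mass            # c = b + NH3
_NH2_MASS = parse_formula("NH2").mass            # z˙ = y − NH2
_WATER_MASS = WATER.mass
_SULFUR = parse_formula("S")
_SULFUR_H = parse_formula("SH")
_GG_PARTIAL = parse_formula("C10H16")            # partial geranylgeranyl fragment
_GERANYLGERANYL = parse_formula("C20H32")

_SERIES_LABEL = {"b": "b", "y": "y", "c": "c", "zdot": "z˙", "p": "p", "d": "d"}


@dataclass(frozen=True)
class LossChannel:
    """One neutral-loss channel derived from a labile modification."""

    lability_class: str
    formula: ChemicalFormula
    species: str                 # e.g. "palmitoyl" or "palmitoyl+S˙"
    series: tuple[str, ...]      # which ion series may shed this neutral
    extrapolated: bool = False   # S–C radical channel beyond the demonstrated chain


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical ion.

    ``losses`` lists modification-derived neutral losses (each adds one
    asterisk to the label).  ``water_delta`` of ±1 marks the p±H2O precursor
    species and is kept separate from ``losses`` so the asterisk convention
    stays unambiguous.  The diagnostic ion d* carries its asterisk as part
    of its canonical name, not as a loss.
    """

    series: str                  # b | y | c | zdot | p | d
    index: int                   # cleavage index; 0 for p and d
    charge: int
    mz: float
    losses: tuple[ChemicalFormula, ...] = ()
    water_delta: int = 0
    label: str = ""

    @property
    def is_backbone(self) -> bool:
        return self.series in ("b", "y", "c", "zdot")


@dataclass(frozen=True)
class ActivationRules:
    """Which ion series and neutral-loss channels an activation produces."""

    activation: str
    backbone_series: tuple[str, ...]
    acyl_loss_series: tuple[str, ...]       # thioester ketene loss
    prenyl_loss_series: tuple[str, ...]     # thioether intact-isoprenoid loss
    etd_sidechain_series: tuple[str, ...]   # S–C bond radical losses
    diagnostic_ions: bool
    charge_reduced_precursors: bool = False
    precursor_water_loss: bool = True
    loss_multiplicity_cap: int = 2

    def __post_init__(self) -> None:
        if self.activation in ("CID", "HCD") and not {"b", "y"} <= set(self.backbone_series):
            raise ValueError(f"{self.activation} rules must contain b and y series")
        if self.activation in ("ETD", "EThcD") and not {"c", "zdot"} <= set(self.backbone_series):
            raise ValueError(f"{self.activation} rules must contain c and z˙ series")

    def channels_for(self, mod: Modification) -> list[LossChannel]:
        """Concrete loss channels contributed by one labile modification."""
        channels: list[LossChannel] = []
        if mod.lability_class == LABILITY_THIOESTER:
            if self.acyl_loss_series:
                channels.append(LossChannel(
                    LABILITY_THIOESTER, mod.delta_formula, mod.name,
                    self.acyl_loss_series,
                ))
            if self.etd_sidechain_series:
                # S–C cleavage sheds acyl + sulfur as a radical, with and
                # without hydrogen transfer; demonstrated for palmitoyl,
                # homologous formulas for other chain lengths.
                extrapolated = str(mod.delta_formula) != "C16H30O"
                base = mod.delta_formula + _SULFUR
                suffix = " (extrapolated)" if extrapolated else ""
                channels.append(LossChannel(
                    LABILITY_THIOESTER,
                    ChemicalFormula(base.element_counts, radical=True),
                    f"{mod.name}+S˙{suffix}",
                    self.etd_sidechain_series, extrapolated,
                ))
                with_h = mod.delta_formula + _SULFUR_H
                channels.append(LossChannel(
                    LABILITY_THIOESTER,
                    ChemicalFormula(with_h.element_counts, radical=True),
                    f"{mod.name}+SH˙{suffix}",
                    self.etd_sidechain_series, extrapolated,
                ))
        elif mod.lability_class == LABILITY_THIOETHER:
            if self.prenyl_loss_series:
                channels.append(LossChannel(
                    LABILITY_THIOETHER, mod.delta_formula, mod.name,
                    self.prenyl_loss_series,
                ))
                if mod.delta_formula.element_counts == _GERANYLGERANYL.element_counts:
                    channels.append(LossChannel(
                        LABILITY_THIOETHER, _GG_PARTIAL,
                        f"{mod.name}-partial", ("p",),
                    ))
        return channels


def default_rules(activation: str) -> ActivationRules:
    """Built-in activation rule sets (see the table in the module docstring)."""
    if activation == "CID":
        return ActivationRules(
            "CID", ("b", "y"),
            acyl_loss_series=("y", "p"),
            prenyl_loss_series=("b", "y", "p"),
            etd_sidechain_series=(),
            diagnostic_ions=True,
        )
    if activation == "HCD":
        return ActivationRules(
            "HCD", ("b", "y"),
            acyl_loss_series=("b", "y", "p"),
            prenyl_loss_series=("b", "y", "p"),
            etd_sidechain_series=(),
            diagnostic_ions=True,
        )
    if activation == "ETD":
        return ActivationRules(
            "ETD", ("c", "zdot"),
            acyl_loss_series=(),
            prenyl_loss_series=(),
            etd_sidechain_series=("p", "zdot"),
            diagnostic_ions=False,
            charge_reduced_precursors=True,
        )
    if activation == "EThcD":
        return ActivationRules(
            "EThcD", ("b", "y", "c", "zdot"),
            acyl_loss_series=("b", "y", "p"),
            prenyl_loss_series=("b", "y", "p"),
            etd_sidechain_series=("p", "zdot"),
            diagnostic_ions=True,
            charge_reduced_precursors=True,
        )
    raise ValueError(f"unknown activation {activation!r}; choose from {ACTIVATIONS}")


def _ion_label(series: str, index: int, charge: int, n_losses: int,
               water_delta: int = 0) -> str:
    name = _SERIES_LABEL[series]
    if series not in ("p", "d"):
        name += str(index)
    name += "*" * n_losses
    if water_delta:
        name += "-H2O" if water_delta < 0 else "+H2O"
    return f"{name}^{charge}+" if charge != 1 else name


def _loss_combinations(
    span_mods: list[tuple[int, Modification]],
    rules: ActivationRules,
    series: str,
) -> list[tuple[ChemicalFormula, ...]]:
    """Distinct loss multisets available to an ion covering ``span_mods``.

    Each labile modification instance in the span contributes at most one
    loss; up to ``loss_multiplicity_cap`` instances may shed simultaneously.
    """
    per_instance: list[list[ChemicalFormula]] = []
    for _pos, mod in span_mods:
        options = [ch.formula for ch in rules.channels_for(mod)
                   if series in ch.series and ch.formula is not _GG_PARTIAL]
        if options:
            per_instance.append(options)
    combos: set[tuple[str, ...]] = set()
    out: list[tuple[ChemicalFormula, ...]] = []
    max_m = min(rules.loss_multiplicity_cap, len(per_instance))
    for m in range(1, max_m + 1):
        for chosen in itertools.combinations(range(len(per_instance)), m):
            for formulas in itertools.product(*(per_instance[i] for i in chosen)):
                key = tuple(sorted(str(f) for f in formulas))
                if key not in combos:
                    combos.add(key)
                    out.append(tuple(sorted(formulas, key=str)))
    return out


def generate_fragments(
    p: Peptidoform,
    rules: ActivationRules,
    max_fragment_charge: int | None = None,
    precursor_charge: int = 2,
) -> list[FragmentIon]:
    """All theoretical ions for a peptidoform under the given rules.

    Backbone ions are emitted for every series at charges
    1..``max_fragment_charge`` (default ``min(2, precursor_charge)``), with
    neutral-loss companions for ions whose residue span covers a labile
    modification.  Precursor species (p, p±H2O, p*, charge-reduced p for
    ETD) and the diagnostic d* follow.
    """
    n = len(p.sequence)
    if n < 2:
        raise ValueError("fragment generation requires a peptide of length >= 2")
    if max_fragment_charge is None:
        max_fragment_charge = max(1, min(2, precursor_charge))

    residue_masses = [AMINO_ACID_MASSES[aa] for aa in p.sequence]
    mod_mass_at: dict[int, float] = {}
    nterm_mod_mass = 0.0
    cterm_mod_mass = 0.0
    for pos, mod in p.modifications:
        if pos == N_TERM:
            nterm_mod_mass += mod.delta_mass
        elif pos == C_TERM:
            cterm_mod_mass += mod.delta_mass
        else:
            mod_mass_at[pos] = mod_mass_at.get(pos, 0.0) + mod.delta_mass

    labile = p.labile_sites()
    ions: list[FragmentIon] = []

    prefix_mass = 0.0
    prefix_mod_mass = nterm_mod_mass
    for i in range(1, n):
        prefix_mass += residue_masses[i - 1]
        prefix_mod_mass += mod_mass_at.get(i, 0.0)
        suffix_index = n - i
        total_mod = sum(mod_mass_at.values()) + nterm_mod_mass + cterm_mod_mass
        suffix_mass = sum(residue_masses[i:])

        neutral = {
            "b": prefix_mass + prefix_mod_mass,
            "c": prefix_mass + prefix_mod_mass + _NH3_MASS,
            "y": suffix_mass + (total_mod - prefix_mod_mass) + _WATER_MASS,
            "zdot": suffix_mass + (total_mod - prefix_mod_mass) + _WATER_MASS - _NH2_MASS,
        }
        span_mods = {
            "nterm": [(pos, mod) for pos, mod in labile if pos <= i],
            "cterm": [(pos, mod) for pos, mod in labile if pos > i],
        }
        for series in rules.backbone_series:
            index = i if series in ("b", "c") else suffix_index
            span = span_mods["nterm"] if series in ("b", "c") else span_mods["cterm"]
            base_neutral = neutral[series]
            loss_sets = _loss_combinations(span, rules, series)
            for charge in range(1, max_fragment_charge + 1):
                ions.append(FragmentIon(
                    series, index, charge,
                    (base_neutral + charge * PROTON_MASS) / charge,
                    label=_ion_label(series, index, charge, 0),
                ))
                for losses in loss_sets:
                    loss_mass = sum(f.mass for f in losses)
                    ions.append(FragmentIon(
                        series, index, charge,
                        (base_neutral - loss_mass + charge * PROTON_MASS) / charge,
                        losses=losses,
                        label=_ion_label(series, index, charge, len(losses)),
                    ))

    ions.extend(precursor_ions(p, precursor_charge, rules))

    if rules.diagnostic_ions:
        seen: set[str] = set()
        for _pos, mod in labile:
            if mod.lability_class == LABILITY_THIOESTER and mod.name not in seen:
                seen.add(mod.name)
                # acylium-type ion: acyl delta + proton, singly charged
                ions.append(FragmentIon(
                    "d", 0, 1, mod.delta_mass + PROTON_MASS, label="d*",
                ))
    return ions


def precursor_ions(
    p: Peptidoform,
    precursor_charge: int,
    rules: ActivationRules,
) -> list[FragmentIon]:
    """Precursor species: p at 1..z (charge-reduced under ETD), p±H2O, p*."""
    if precursor_charge < 1:
        raise ValueError("precursor_charge must be >= 1")
    neutral = peptide_neutral_mass(p)
    ions: list[FragmentIon] = []

    for z in range(1, precursor_charge + 1):
        if rules.charge_reduced_precursors and z < precursor_charge:
            # electron transfer keeps all protons: [M + nH]^(z)+ at reduced z
            reduced_mz = (neutral + precursor_charge * PROTON_MASS) / z
            ions.append(FragmentIon(
                "p", 0, z, reduced_mz,
                label=_ion_label("p", 0, z, 0) + "(charge-reduced)",
            ))
        else:
            ions.append(FragmentIon(
                "p", 0, z, (neutral + z * PROTON_MASS) / z,
                label=_ion_label("p", 0, z, 0),
            ))

    z = precursor_charge
    if rules.precursor_water_loss:
        for delta in (-1, +1):
            ions.append(FragmentIon(
                "p", 0, z,
                (neutral + delta * _WATER_MASS + z * PROTON_MASS) / z,
                water_delta=delta,
                label=_ion_label("p", 0, z, 0, water_delta=delta),
            ))

    emitted: set[str] = set()
    for _pos, mod in p.labile_sites():
        for channel in rules.channels_for(mod):
            if "p" not in channel.series:
                continue
            key = channel.species
            if key in emitted:
                continue
            emitted.add(key)
            ions.append(FragmentIon(
                "p", 0, z,
                (neutral - channel.formula.mass + z * PROTON_MASS) / z,
                losses=(channel.formula,),
                label=_ion_label("p", 0, z, 1),
            ))
    return ions


def write_fragment_tsv(
    p: Peptidoform,
    ions: Sequence[FragmentIon],
    stream: TextIO,
) -> None:
    """Write a fragment table: peptidoform, series, index, charge, losses,
    theoretical m/z, label.  Rows sorted by m/z for readability."""
    stream.write("peptidoform\tseries\tindex\tcharge\tlosses\ttheoretical_mz\tlabel\n")
    for ion in sorted(ions, key=lambda f: f.mz):
        losses = "+".join(str(f) for f in ion.losses) or "-"
        stream.write(
            f"{p}\t{ion.series}\t{ion.index}\t{ion.charge}\t{losses}\t"
            f"{ion.mz:.5f}\t{ion.label}\n"
        )
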