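"""Chemical formulas, monoisotopic masses and the modification registry.

Every mass in the package derives from the small set of monoisotopic atomic
masses below (CODATA/NIST).  Electron mass is neglected throughout, for
neutral and radical species alike; radical (odd-electron) species carry a
``radical`` flag that affects labeling only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "WATER",
    "AMINO_ACID_FORMULAS",
    "ChemicalFormula",
    "Modification",
    "Peptidoform",
    "parse_formula",
    "monoisotopic_mass",
    "peptide_neutral_mass",
    "peptide_formula",
    "mz",
    "neutral_mass_from_mz",
    "registry_lookup",
    "load_registry",
    "default_registry",
]

#: Monoisotopic atomic masses in Da (12C scale).
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton in Da (H minus one electron).
PROTON_MASS = 1.007276466

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula text."""


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition restricted to C, H, N, O, S, P.

    Parameters
    ----------
    element_counts
        Mapping of element symbol to a non-negative count.  At least one
        element must have a positive count.
    radical
        Marks odd-electron species (e.g. the S–C cleavage losses seen under
        electron transfer dissociation).  Affects the label only, never the
        mass, since electron mass is neglected.
    """

    element_counts: Mapping[str, int]
    radical: bool = False

    def __post_init__(self) -> None:
        counts = {e: int(n) for e, n in self.element_counts.items() if n}
        for element, n in counts.items():
            if element not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element {element!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {element!r}")
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "element_counts", counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(ATOMIC_MASSES[e] * n for e, n in self.element_counts.items())

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.element_counts)
        for e, n in other.element_counts.items():
            counts[e] = counts.get(e, 0) + n
        return ChemicalFormula(counts, radical=self.radical or other.radical)

    def __mul__(self, k: int) -> "ChemicalFormula":
        return ChemicalFormula({e: n * k for e, n in self.element_counts.items()},
                               radical=self.radical)

    __rmul__ = __mul__

    def __str__(self) -> str:
        order = ["C", "H", "N", "O", "S", "P"]
        parts = []
        for e in order:
            n = self.element_counts.get(e, 0)
            if n:
                parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts) + ("˙" if self.radical else "")


def parse_formula(text: str, radical: bool = False) -> ChemicalFormula:
    """Parse a Hill-style formula string such as ``"C16H30O"``.

    Element symbols may carry an optional positive integer count.  Symbols
    outside the supported set raise :class:`FormulaError` naming the token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        element, digits = m.group(1), m.group(2)
        if element not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element {element}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ChemicalFormula(counts, radical=radical)


def monoisotopic_mass(f: Union[ChemicalFormula, str]) -> float:
    """Monoisotopic mass (Da) of a formula or formula string."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


WATER = parse_formula("H2O")
_AMMONIA = parse_formula("NH3")

#: Residue (i.e. dehydrated) elemental compositions of the 20 standard
#: amino acids.
AMINO_ACID_FORMULAS: dict[str, ChemicalFormula] = {
    "G": parse_formula("C2H3NO"),
    "A": parse_formula("C3H5NO"),
    "S": parse_formula("C3H5NO2"),
    "P": parse_formula("C5H7NO"),
    "V": parse_formula("C5H9NO"),
    "T": parse_formula("C4H7NO2"),
    "C": parse_formula("C3H5NOS"),
    "L": parse_formula("C6H11NO"),
    "I": parse_formula("C6H11NO"),
    "N": parse_formula("C4H6N2O2"),
    "D": parse_formula("C4H5NO3"),
    "Q": parse_formula("C5H8N2O2"),
    "K": parse_formula("C6H12N2O"),
    "E": parse_formula("C5H7NO3"),
    "M": parse_formula("C5H9NOS"),
    "H": parse_formula("C6H7N3O"),
    "F": parse_formula("C9H9NO"),
    "R": parse_formula("C6H12N4O"),
    "Y": parse_formula("C9H9NO2"),
    "W": parse_formula("C11H10N2O"),
}

AMINO_ACID_MASSES: dict[str, float] = {
    aa: f.mass for aa, f in AMINO_ACID_FORMULAS.items()
}

#: Lability classes controlling which neutral-loss channels apply.
LABILITY_THIOESTER = "thioester_acyl"
LABILITY_THIOETHER = "thioether_prenyl"
LABILITY_STABLE = "stable"

POSITION_ANYWHERE = "anywhere"
POSITION_PROTEIN_NTERM = "protein-N-term"
POSITION_PEPTIDE_NTERM = "peptide-N-term"

N_TERM = "N-term"
C_TERM = "C-term"


@dataclass(frozen=True)
class Modification:
    """A covalent modification applied to a residue or terminus.

    ``lability_class`` drives the fragmentation model: ``thioester_acyl``
    (long-chain S-acyl groups on Cys, lost as a ketene under collisional
    activation), ``thioether_prenyl`` (farnesyl/geranylgeranyl, lost intact),
    or ``stable`` (no loss channel).
    """

    name: str
    delta_formula: ChemicalFormula
    target_residues: frozenset[str]
    position_rule: str = POSITION_ANYWHERE
    lability_class: str = LABILITY_STABLE

    @property
    def delta_mass(self) -> float:
        return self.delta_formula.mass

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with localized modifications.

    Positions are 1-based residue indices (matching the Cys14/Cys18
    convention used when naming protein sites) or the terminus tags
    ``"N-term"`` / ``"C-term"``.
    """

    sequence: str
    modifications: tuple = ()
    protein_context: tuple | None = None  # (accession, start position)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in AMINO_ACID_FORMULAS:
                raise ValueError(
                    f"unknown or unsupported residue {aa!r} "
                    "(B/Z/X/U and non-standard codes are rejected)"
                )
        mods = tuple(self.modifications)
        seen_residue_positions = set()
        for pos, mod in mods:
            if pos in (N_TERM, C_TERM):
                continue
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            residue = self.sequence[pos - 1]
            if mod.target_residues and residue not in mod.target_residues:
                raise ValueError(
                    f"{mod.name} does not target residue {residue!r} at {pos}"
                )
            if pos in seen_residue_positions:
                raise ValueError(f"two modifications on residue position {pos}")
            seen_residue_positions.add(pos)
        object.__setattr__(self, "modifications", mods)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self)

    def residue_mods(self) -> list[tuple[int, Modification]]:
        """Modifications with integer positions, sorted by position."""
        return sorted(
            ((p, m) for p, m in self.modifications if isinstance(p, int)),
            key=lambda pm: pm[0],
        )

    def labile_sites(self, lability_class: str | None = None) -> list[tuple[int, Modification]]:
        """Residue positions carrying a labile modification."""
        out = []
        for pos, mod in self.residue_mods():
            if mod.lability_class == LABILITY_STABLE:
                continue
            if lability_class is None or mod.lability_class == lability_class:
                out.append((pos, mod))
        return out

    def __str__(self) -> str:
        from .notation import format_peptidoform

        return format_peptidoform(self)


def peptide_formula(p: Peptidoform) -> ChemicalFormula:
    """Full elemental composition of a peptidoform (residues + H2O + mods)."""
    total = WATER
    for aa in p.sequence:
        total = total + AMINO_ACID_FORMULAS[aa]
    for _pos, mod in p.modifications:
        total = total + mod.delta_formula
    return total


def peptide_neutral_mass(p: Peptidoform) -> float:
    """Monoisotopic neutral mass in Da: residues + H2O + modification deltas."""
    mass = WATER.mass
    for aa in p.sequence:
        mass += AMINO_ACID_MASSES[aa]
    for _pos, mod in p.modifications:
        mass += mod.delta_mass
    return mass


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated species: ``(M + z * proton) / z``."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def neutral_mass_from_mz(observed_mz: float, charge: int) -> float:
    """Invert :func:`mz`."""
    if charge <= 0:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return observed_mz * charge - charge * PROTON_MASS


# ---------------------------------------------------------------------------
# Modification registry


def _registry_path() -> Path:
    return Path(str(resources.files("lipopept").joinpath("data/modifications.tsv")))


def load_registry(path: str | Path | None = None) -> dict[str, Modification]:
    """Load a modification registry from TSV.

    Columns: name, formula, delta_mass, targets, position_rule,
    lability_class.  ``delta_mass`` is informational; the formula is
    authoritative.  ``targets`` is a string of one-letter codes ('*' = any).
    """
    path = _registry_path() if path is None else Path(path)
    registry: dict[str, Modification] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "formula", "delta_mass", "targets",
                    "position_rule", "lability_class"]
        if header != expected:
            raise ValueError(f"bad registry header {header!r}; expected {expected!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, formula, _delta, targets, position_rule, lability = line.split("\t")
            targets_set = frozenset() if targets == "*" else frozenset(targets)
            registry[name] = Modification(
                name=name,
                delta_formula=parse_formula(formula),
                target_residues=targets_set,
                position_rule=position_rule,
                lability_class=lability,
            )
    if not registry:
        raise ValueError(f"empty modification registry: {path}")
    return registry


_DEFAULT_REGISTRY: dict[str, Modification] | None = None


def default_registry() -> dict[str, Modification]:
    """The built-in registry (lipid PTMs plus common search modifications)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_registry()
    return _DEFAULT_REGISTRY


def registry_lookup(name: str, registry: Mapping[str, Modification] | None = None) -> Modification:
    """Look up a modification by name.

    Raises ``KeyError`` listing the available names when absent.
    """
    reg = default_registry() if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown modification {name!r}; registry contains: "
            + ", ".join(sorted(reg))
        ) from None
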