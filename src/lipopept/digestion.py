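"""In-silico proteolysis and variable-modification peptidoform enumeration.

The digestion rule is strict trypsin (cleavage C-terminal to K/R, suppressed
before proline), with optional protein N-terminal methionine clipping; this
defines the search space used for identifying lipidated tryptic peptides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from pyteomics import fasta as _fasta

from .chem import AMINO_ACID_FORMULAS, Modification, Peptidoform

__all__ = [
    "DigestParams",
    "VariableModSpec",
    "DigestedPeptide",
    "digest",
    "enumerate_peptidoforms",
    "read_fasta",
]


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings.

    Defaults mirror a strict tryptic search: two missed cleavages, peptide
    length 7–50, protein N-terminal Met clipping enabled.
    """

    enzyme: str = "trypsin_strict"
    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    clip_nterm_met: bool = True

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin_strict":
            raise ValueError(f"unsupported enzyme rule {self.enzyme!r}")
        if not (0 <= self.missed_cleavages <= 5):
            raise ValueError("missed_cleavages must be in 0..5")
        if self.min_length > self.max_length or self.min_length < 1:
            raise ValueError("require 1 <= min_length <= max_length")


@dataclass(frozen=True)
class VariableModSpec:
    """Set of variable modifications and the per-peptide cap on their count."""

    mods: tuple[Modification, ...] = ()
    max_mods_per_peptide: int = 3

    def __post_init__(self) -> None:
        if self.max_mods_per_peptide < 0:
            raise ValueError("max_mods_per_peptide must be >= 0")
        object.__setattr__(self, "mods", tuple(self.mods))


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    start: int  # 1-based position in the protein
    missed_cleavages: int


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that the bond after sequence[i] is cleaved.

    Strict trypsin: after K or R, unless the next residue is P.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def _digest_one(sequence: str, params: DigestParams, offset: int) -> Iterator[DigestedPeptide]:
    sites = _cleavage_sites(sequence)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    n_segments = len(bounds) - 1
    for i in range(n_segments):
        for j in range(i + 1, min(i + 2 + params.missed_cleavages, n_segments + 1)):
            pep = sequence[bounds[i]:bounds[j]]
            if params.min_length <= len(pep) <= params.max_length:
                yield DigestedPeptide(pep, bounds[i] + offset + 1, j - i - 1)


def digest(protein_sequence: str, params: DigestParams | None = None) -> list[DigestedPeptide]:
    """Tryptic peptides of a protein with their start positions.

    When ``clip_nterm_met`` is set and the protein starts with methionine,
    peptides from the Met-clipped form are emitted as well (the search
    considers both protein forms); duplicates by (sequence, start) are
    removed.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    for aa in protein_sequence:
        if aa not in AMINO_ACID_FORMULAS:
            raise ValueError(f"unsupported residue {aa!r} in protein sequence")
    params = DigestParams() if params is None else params

    peptides = list(_digest_one(protein_sequence, params, offset=0))
    if params.clip_nterm_met and protein_sequence.startswith("M"):
        peptides.extend(_digest_one(protein_sequence[1:], params, offset=1))
    seen: set[tuple[str, int]] = set()
    out = []
    for pep in peptides:
        key = (pep.sequence, pep.start)
        if key not in seen:
            seen.add(key)
            out.append(pep)
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def _eligible(mod: Modification, peptide: str, pos: int) -> bool:
    residue = peptide[pos - 1]
    if mod.target_residues and residue not in mod.target_residues:
        return False
    if mod.position_rule == "peptide-N-term" and pos != 1:
        return False
    # protein-N-term eligibility is decided by the caller via protein context;
    # at the bare-peptide level it behaves like peptide-N-term.
    if mod.position_rule == "protein-N-term" and pos != 1:
        return False
    return True


def enumerate_peptidoforms(
    peptide: str,
    spec: VariableModSpec,
    protein_context: tuple | None = None,
) -> list[Peptidoform]:
    """All peptidoforms of ``peptide`` under a variable-modification spec.

    Each eligible site independently takes one of {unmodified} ∪ {applicable
    mods}; combinations exceeding ``max_mods_per_peptide`` total mods are
    dropped.  Ordering is deterministic: sites left to right, modification
    names alphabetically, unmodified state first.
    """
    site_options: list[tuple[int, list[Modification | None]]] = []
    for pos in range(1, len(peptide) + 1):
        applicable = sorted(
            (m for m in spec.mods if _eligible(m, peptide, pos)),
            key=lambda m: m.name,
        )
        if applicable:
            site_options.append((pos, [None] + applicable))

    forms: list[Peptidoform] = []
    for choice in itertools.product(*(opts for _pos, opts in site_options)):
        assigned = [
            (site_options[k][0], mod)
            for k, mod in enumerate(choice)
            if mod is not None
        ]
        if len(assigned) > spec.max_mods_per_peptide:
            continue
        forms.append(Peptidoform(peptide, tuple(assigned), protein_context))
    return forms


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file.

    Returns ``(accession, sequence)`` pairs; the accession is the first
    whitespace-delimited token of the header.
    """
    records = []
    with _fasta.read(str(path)) as reader:
        for header, sequence in reader:
            accession = header.split()[0] if header.split() else header
            records.append((accession, sequence.upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
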