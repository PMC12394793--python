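"""Miniature variable-modification database search with target-decoy FDR.

The search space (strict tryptic digestion, variable lipid modifications,
20 ppm precursor/fragment tolerances) mirrors a lipid-aware closed search;
scoring is deliberately simple — matched backbone + neutral-loss +
diagnostic ion counting with a matched-intensity tie-break — because the
claim of this package is the lipidated-peptide search space and loss-ion
matching, not parity with a production search engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import Modification, Peptidoform, neutral_mass_from_mz, peptide_neutral_mass
from .digestion import DigestParams, VariableModSpec, digest, enumerate_peptidoforms, read_fasta
from .fragments import default_rules, generate_fragments
from .annotation import match_peaks
from .spectra import Spectrum

__all__ = [
    "SearchParams",
    "PSM",
    "CandidateIndex",
    "build_index",
    "search_spectrum",
    "compute_fdr",
    "run_search",
]

DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 20.0
    digest: DigestParams = field(default_factory=DigestParams)
    mods: VariableModSpec = field(default_factory=VariableModSpec)
    decoy_strategy: str = "reversed"
    fdr_threshold: float = 0.01
    count_loss_ions: bool = True  # lipid-specific evidence contributes to the score
    min_matched_ions: int = 4     # PSMs with fewer matched ions are not reported

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.decoy_strategy != "reversed":
            raise ValueError("only the 'reversed' decoy strategy is supported")


@dataclass
class PSM:
    spectrum_id: str
    peptidoform: Peptidoform
    charge: int
    score: float
    is_decoy: bool
    protein: str
    precursor_ppm: float
    q_value: float | None = None
    charge_assumed: bool = False  # charge was unknown and guessed


@dataclass
class CandidateIndex:
    """Peptidoforms keyed by neutral mass (sorted for window queries)."""

    masses: np.ndarray
    peptidoforms: list[Peptidoform]
    proteins: list[str]
    is_decoy: np.ndarray

    def __len__(self) -> int:
        return int(self.masses.size)

    def window(self, neutral_mass: float, tol_ppm: float) -> range:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self.masses, neutral_mass - tol, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + tol, side="right"))
        return range(lo, hi)


def reverse_decoy(sequence: str) -> str:
    """Per-protein reversal with the C-terminal residue fixed in place,
    preserving the tryptic C-terminus of decoy peptides."""
    if len(sequence) < 2:
        return sequence
    return sequence[-2::-1] + sequence[-1]


def build_index(
    fasta_path: str | Path | None,
    params: SearchParams,
    proteins: Sequence[tuple[str, str]] | None = None,
) -> CandidateIndex:
    """Enumerate all target + reversed-decoy peptidoforms within bounds.

    ``proteins`` may be passed directly instead of a FASTA path.
    """
    if proteins is None:
        if fasta_path is None:
            raise ValueError("either fasta_path or proteins is required")
        proteins = read_fasta(fasta_path)
    if not proteins:
        raise ValueError("empty protein list")

    entries: list[tuple[float, Peptidoform, str, bool]] = []
    for accession, sequence in proteins:
        for decoy in (False, True):
            acc = DECOY_PREFIX + accession if decoy else accession
            seq = reverse_decoy(sequence) if decoy else sequence
            seen: set[str] = set()
            for pep in digest(seq, params.digest):
                if pep.sequence in seen:
                    continue
                seen.add(pep.sequence)
                for form in enumerate_peptidoforms(
                    pep.sequence, params.mods, protein_context=(acc, pep.start)
                ):
                    entries.append((peptide_neutral_mass(form), form, acc, decoy))

    entries.sort(key=lambda e: e[0])
    return CandidateIndex(
        masses=np.array([e[0] for e in entries]),
        peptidoforms=[e[1] for e in entries],
        proteins=[e[2] for e in entries],
        is_decoy=np.array([e[3] for e in entries], dtype=bool),
    )


def _score_candidate(
    spectrum: Spectrum,
    form: Peptidoform,
    charge: int,
    params: SearchParams,
) -> float:
    activation = spectrum.activation or "HCD"
    rules = default_rules(activation)
    theoretical = generate_fragments(form, rules, precursor_charge=charge)
    if not params.count_loss_ions:
        theoretical = [
            ion for ion in theoretical
            if not ion.losses and ion.series != "d"
        ]
    matches = match_peaks(spectrum, theoretical, params.fragment_tol_ppm)
    counted = [m for m in matches if m.fragment.is_backbone
               or m.fragment.losses or m.fragment.series == "d"]
    total = float(spectrum.intensity.sum())
    matched_idx = {m.peak_index for m in matches}
    mif = (
        float(spectrum.intensity[sorted(matched_idx)].sum()) / total
        if total > 0 and matched_idx else 0.0
    )
    return len(counted) + 0.01 * mif


def search_spectrum(
    spectrum: Spectrum,
    index: CandidateIndex,
    params: SearchParams,
    max_rank: int = 1,
) -> list[PSM]:
    """Score all candidates within the precursor window; return top PSMs.

    An unknown precursor charge is handled by trying charges 2-4 and
    flagging the assumption on the resulting PSMs.
    """
    if spectrum.precursor_mz is None:
        raise ValueError(f"spectrum {spectrum.scan_id!r} has no precursor m/z")
    charges = (
        [spectrum.precursor_charge]
        if spectrum.precursor_charge
        else [2, 3, 4]
    )
    assumed = spectrum.precursor_charge is None

    psms: list[PSM] = []
    for charge in charges:
        neutral = neutral_mass_from_mz(spectrum.precursor_mz, charge)
        for i in index.window(neutral, params.precursor_tol_ppm):
            form = index.peptidoforms[i]
            score = _score_candidate(spectrum, form, charge, params)
            if score < params.min_matched_ions:
                continue
            psms.append(PSM(
                spectrum_id=spectrum.scan_id,
                peptidoform=form,
                charge=charge,
                score=score,
                is_decoy=bool(index.is_decoy[i]),
                protein=index.proteins[i],
                precursor_ppm=1e6 * (neutral - index.masses[i]) / index.masses[i],
                charge_assumed=assumed,
            ))
    psms.sort(key=lambda p: (-p.score, str(p.peptidoform)))
    return psms[:max_rank] if max_rank else psms


def compute_fdr(psms: list[PSM]) -> list[PSM]:
    """Assign target-decoy q-values.

    PSMs are sorted by score descending; at each threshold the running FDR
    is decoys/targets, and the q-value is the monotone minimum of all FDRs
    at equal-or-lower scores.  With zero targets every q-value is 1.
    """
    ordered = sorted(psms, key=lambda p: -p.score)
    n_targets = 0
    n_decoys = 0
    fdrs: list[float] = []
    for psm in ordered:
        if psm.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        fdrs.append(min(1.0, n_decoys / n_targets) if n_targets else 1.0)
    running_min = 1.0
    for i in range(len(ordered) - 1, -1, -1):
        running_min = min(running_min, fdrs[i])
        ordered[i].q_value = running_min
    return ordered


def run_search(
    spectra: Iterable[Spectrum],
    index: CandidateIndex,
    params: SearchParams,
) -> list[PSM]:
    """Search every MS2 spectrum, keep the top hit each, and assign q-values."""
    top_hits: list[PSM] = []
    for spectrum in spectra:
        if spectrum.ms_level != 2:
            continue
        hits = search_spectrum(spectrum, index, params, max_rank=1)
        if hits:
            top_hits.append(hits[0])
    return compute_fdr(top_hits)
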