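"""Spectrum annotation, ion coverage, and labile-modification localization.

Ion coverage is defined over backbone cleavage sites: site i (1..n-1) is
covered when any matched sequence ion cleaving there exists — b/c of index i
or y/z˙ of index n-i — including neutral-loss variants, which still carry
sequence information.  Precursor (p/p*) and diagnostic (d*) matches never
count toward coverage.

Localization scores each assignment of a modification multiset to candidate
sites by the number of matched site-determining ions (ions whose m/z is
unique to that assignment), with the matched-intensity fraction as a small
tie-break term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import Modification, Peptidoform
from .fragments import ActivationRules, FragmentIon, generate_fragments
from .spectra import Spectrum

__all__ = [
    "PeakMatch",
    "AnnotationResult",
    "LocalizationResult",
    "match_peaks",
    "ion_coverage",
    "annotate",
    "localize",
]


@dataclass(frozen=True)
class PeakMatch:
    fragment: FragmentIon
    observed_mz: float
    observed_intensity: float
    ppm_error: float
    peak_index: int
    shared: bool = False  # observed peak also satisfies another theoretical ion


@dataclass
class AnnotationResult:
    peptidoform: Peptidoform
    spectrum_id: str
    matches: list[PeakMatch]
    ion_coverage: float
    per_series_coverage: dict[str, float]
    matched_intensity_fraction: float


@dataclass
class LocalizationResult:
    ranked: list[tuple[Peptidoform, float]]
    delta_score: float
    site_determining_matches: list[PeakMatch]

    @property
    def best(self) -> Peptidoform:
        return self.ranked[0][0]

    @property
    def ambiguous(self) -> bool:
        return self.delta_score == 0.0


def match_peaks(
    spectrum: Spectrum,
    theoretical: Sequence[FragmentIon],
    tol_ppm: float = 20.0,
) -> list[PeakMatch]:
    """Match theoretical ions to observed peaks within a ppm tolerance.

    Each theoretical ion takes the observed peak minimizing |ppm error|;
    one observed peak may satisfy several theoretical ions (such matches are
    retained and flagged ``shared``).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz = spectrum.mz
    matches: list[PeakMatch] = []
    if mz.size == 0:
        return matches
    used: dict[int, int] = {}
    for ion in theoretical:
        tol = ion.mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(mz, ion.mz - tol, side="left"))
        hi = int(np.searchsorted(mz, ion.mz + tol, side="right"))
        if lo == hi:
            continue
        window = mz[lo:hi]
        best = lo + int(np.argmin(np.abs(window - ion.mz)))
        observed = float(mz[best])
        matches.append(PeakMatch(
            fragment=ion,
            observed_mz=observed,
            observed_intensity=float(spectrum.intensity[best]),
            ppm_error=1e6 * (observed - ion.mz) / ion.mz,
            peak_index=best,
        ))
        used[best] = used.get(best, 0) + 1
    if any(count > 1 for count in used.values()):
        matches = [
            m if used[m.peak_index] == 1 else
            PeakMatch(m.fragment, m.observed_mz, m.observed_intensity,
                      m.ppm_error, m.peak_index, shared=True)
            for m in matches
        ]
    return matches


def _covered_sites(matches: Iterable[PeakMatch], n: int,
                   include_losses: bool = True) -> dict[str, set[int]]:
    per_series: dict[str, set[int]] = {}
    for m in matches:
        ion = m.fragment
        if not ion.is_backbone:
            continue
        if ion.losses and not include_losses:
            continue
        site = ion.index if ion.series in ("b", "c") else n - ion.index
        if 1 <= site <= n - 1:
            per_series.setdefault(ion.series, set()).add(site)
    return per_series


def ion_coverage(matches: Iterable[PeakMatch], peptide_length: int,
                 include_losses: bool = True) -> float:
    """Fraction of backbone cleavage sites supported by a matched sequence ion."""
    if peptide_length < 2:
        raise ValueError("ion coverage requires peptide length >= 2")
    per_series = _covered_sites(matches, peptide_length, include_losses)
    covered = set().union(*per_series.values()) if per_series else set()
    return len(covered) / (peptide_length - 1)


def annotate(
    spectrum: Spectrum,
    peptidoform: Peptidoform,
    rules: ActivationRules,
    tol_ppm: float = 20.0,
    precursor_charge: int | None = None,
    include_losses_in_coverage: bool = True,
) -> AnnotationResult:
    """Annotate one spectrum against one peptidoform."""
    charge = precursor_charge or spectrum.precursor_charge or 2
    theoretical = generate_fragments(peptidoform, rules, precursor_charge=charge)
    matches = match_peaks(spectrum, theoretical, tol_ppm)
    n = len(peptidoform)
    per_series_sets = _covered_sites(matches, n, include_losses_in_coverage)
    per_series = {s: len(sites) / (n - 1) for s, sites in per_series_sets.items()}
    coverage = ion_coverage(matches, n, include_losses_in_coverage)
    total = float(spectrum.intensity.sum())
    matched_idx = {m.peak_index for m in matches}
    mif = (
        float(spectrum.intensity[sorted(matched_idx)].sum()) / total
        if total > 0 and matched_idx else 0.0
    )
    return AnnotationResult(
        peptidoform=peptidoform,
        spectrum_id=spectrum.scan_id,
        matches=matches,
        ion_coverage=coverage,
        per_series_coverage=per_series,
        matched_intensity_fraction=mif,
    )


def candidate_assignments(
    peptide: str,
    mods: Sequence[Modification],
    candidate_sites: Sequence[int],
) -> list[Peptidoform]:
    """All distinct assignments of a modification multiset to candidate sites."""
    assignments: set[tuple[tuple[int, str], ...]] = set()
    forms: list[Peptidoform] = []
    for sites in itertools.permutations(candidate_sites, len(mods)):
        key = tuple(sorted(zip(sites, (m.name for m in mods))))
        if key in assignments:
            continue
        assignments.add(key)
        forms.append(Peptidoform(
            peptide, tuple(sorted(zip(sites, mods), key=lambda pm: pm[0]))
        ))
    forms.sort(key=str)
    return forms


def localize(
    spectrum: Spectrum,
    peptide: str,
    mods: Sequence[Modification],
    candidate_sites: Sequence[int],
    rules: ActivationRules,
    tol_ppm: float = 20.0,
    precursor_charge: int | None = None,
) -> LocalizationResult:
    """Rank assignments of ``mods`` to ``candidate_sites`` against a spectrum.

    Score = number of matched site-determining ions + 0.01 x matched-intensity
    fraction.  ``delta_score`` is the gap between the top two assignments;
    zero means the spectrum cannot distinguish them.
    """
    if not candidate_sites:
        raise ValueError("localization requires candidate sites")
    forms = candidate_assignments(peptide, mods, candidate_sites)
    if len(forms) < 2:
        raise ValueError("localization requires >=2 candidate assignments")
    charge = precursor_charge or spectrum.precursor_charge or 2

    theoretical = [generate_fragments(f, rules, precursor_charge=charge) for f in forms]
    # an ion is site-determining for a form when its m/z occurs in no other form
    keysets = [frozenset(round(ion.mz, 4) for ion in ions) for ions in theoretical]
    scored: list[tuple[Peptidoform, float, list[PeakMatch]]] = []
    for k, (form, ions) in enumerate(zip(forms, theoretical)):
        others: set[float] = set().union(*(keysets[j] for j in range(len(forms)) if j != k))
        determining_mz = {round(ion.mz, 4) for ion in ions} - others
        ann = annotate(spectrum, form, rules, tol_ppm, precursor_charge=charge)
        unique_matches = [
            m for m in ann.matches if round(m.fragment.mz, 4) in determining_mz
        ]
        score = len(unique_matches) + 0.01 * ann.matched_intensity_fraction
        scored.append((form, score, unique_matches))

    scored.sort(key=lambda t: (-t[1], str(t[0])))
    ranked = [(form, score) for form, score, _m in scored]
    delta = ranked[0][1] - ranked[1][1]
    # a pure tie-break difference (< 1 ion) is not positional evidence
    if delta < 1.0 and len(scored[0][2]) == len(scored[1][2]) == 0:
        delta = 0.0
    return LocalizationResult(
        ranked=ranked,
        delta_score=delta,
        site_determining_matches=scored[0][2],
    )
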