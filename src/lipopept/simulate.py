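"""Synthetic spectra, chromatograms and fixture bundles with known truth.

Everything here is simulation: spectra emulate the qualitative activation
patterns seen for S-acylated peptides (dominant y-ions under HCD with loss
companions for fragments spanning the acyl site; a dominant p* under CID at
charge 3+; c/z˙ ions plus S–C radical precursor losses under ETD), and XIC
fixtures are Gaussian elution peaks with log-normal replicate scatter.
Chromatographic peak-shape realism and isotope envelopes are deliberately
out of scope.

RNG contract: each simulator consumes a single ``numpy.random.default_rng``
stream seeded from its ``seed`` parameter, drawing in a fixed documented
order (subsampling mask first, then intensities, then m/z jitter, then
noise peaks), so any step can be recomputed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import (
    Modification,
    Peptidoform,
    mz as _mz,
    peptide_neutral_mass,
    registry_lookup,
)
from .fragments import FragmentIon, default_rules, generate_fragments
from .spectra import Spectrum, write_mgf, write_mzml

__all__ = [
    "SpectrumSimParams",
    "QuantDataset",
    "simulate_spectrum",
    "simulate_quant_dataset",
    "write_fixture_files",
    "toy_proteome",
]

_AA_POOL = "ADEFGHILNPQVW"  # no K/R (cleavage sites added explicitly), no C/M


@dataclass(frozen=True)
class SpectrumSimParams:
    """Knobs for one simulated MS2 spectrum."""

    peptidoform: Peptidoform
    activation: str = "HCD"
    precursor_charge: int = 2
    ion_sampling_fraction: float = 1.0
    loss_intensity_factor: float = 0.8   # *-ion intensity relative to parent series
    noise_peak_count: int = 0
    noise_intensity_range: tuple[float, float] = (1.0, 50.0)
    mz_jitter_ppm_sigma: float = 0.0
    base_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ion_sampling_fraction <= 1):
            raise ValueError("ion_sampling_fraction must be in (0, 1]")
        if self.mz_jitter_ppm_sigma > 10:
            raise ValueError("mz jitter sigma above 10 ppm is not supported")


def _series_weight(ion: FragmentIon, activation: str, precursor_charge: int,
                   loss_factor: float) -> float:
    """Relative intensity weighting reproducing the activation patterns."""
    if activation == "CID":
        base = {"b": 0.9, "y": 1.0, "p": 0.6, "d": 0.5}.get(ion.series, 0.3)
        if ion.losses:
            # palmitoyl loss dominates the precursor at higher charge states
            if ion.series == "p" and precursor_charge >= 3:
                base = 3.0
            else:
                base *= 0.25
    elif activation in ("HCD", "EThcD"):
        base = {"b": 0.4, "y": 1.0, "p": 0.4, "d": 0.6,
                "c": 0.5, "zdot": 0.5}.get(ion.series, 0.3)
        if ion.losses:
            base *= loss_factor
    else:  # ETD
        base = {"c": 1.0, "zdot": 0.9, "p": 0.8}.get(ion.series, 0.3)
        if ion.losses:
            base *= 1.5 if ion.series == "p" else 0.5
    return base


def simulate_spectrum(
    params: SpectrumSimParams,
) -> tuple[Spectrum, list[FragmentIon]]:
    """Simulate one centroided MS2 spectrum; returns it with the retained
    ground-truth ion list."""
    rng = np.random.default_rng(params.seed)
    rules = default_rules(params.activation)
    theoretical = generate_fragments(
        params.peptidoform, rules, precursor_charge=params.precursor_charge
    )
    keep_mask = rng.random(len(theoretical)) < params.ion_sampling_fraction
    retained = [ion for ion, keep in zip(theoretical, keep_mask) if keep]

    weights = np.array([
        _series_weight(ion, params.activation, params.precursor_charge,
                       params.loss_intensity_factor)
        for ion in retained
    ])
    intensities = params.base_intensity * weights * rng.lognormal(
        mean=0.0, sigma=0.3, size=len(retained)
    )
    mzs = np.array([ion.mz for ion in retained])
    if params.mz_jitter_ppm_sigma > 0:
        mzs = mzs * (1.0 + rng.normal(0.0, params.mz_jitter_ppm_sigma,
                                      size=mzs.size) * 1e-6)

    if params.noise_peak_count:
        hi_mz = float(mzs.max()) + 200.0 if mzs.size else 2000.0
        noise_mz = rng.uniform(120.0, hi_mz, size=params.noise_peak_count)
        lo, hi = params.noise_intensity_range
        noise_intensity = rng.uniform(lo, hi, size=params.noise_peak_count)
        mzs = np.concatenate([mzs, noise_mz])
        intensities = np.concatenate([intensities, noise_intensity])

    neutral = peptide_neutral_mass(params.peptidoform)
    spectrum = Spectrum(
        scan_id=f"sim:{params.peptidoform}/{params.precursor_charge}:{params.seed}",
        mz=mzs,
        intensity=intensities,
        ms_level=2,
        precursor_mz=_mz(neutral, params.precursor_charge),
        precursor_charge=params.precursor_charge,
        activation=params.activation,
        retention_time=600.0,
    )
    return spectrum, retained


# ---------------------------------------------------------------------------
# Quantification fixtures


@dataclass
class QuantDataset:
    """Simulated spike-in assay: MS1 runs per condition plus ground truth."""

    target_mz: float
    runs: dict[str, list[list[Spectrum]]]   # condition -> replicate -> MS1 scans
    true_areas: dict[str, list[float]]
    control_label: str = "control"


def simulate_quant_dataset(
    true_loss_fraction: float = 0.5,
    n_replicates: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    control_mean_area: float = 1.0e6,
    n_control_replicates: int | None = None,
    target_mz: float = 650.0,
    treated_label: str = "treated",
) -> QuantDataset:
    """Control vs treated XIC runs with a known fractional abundance loss.

    Each replicate run is a train of MS1 scans (1 s apart) holding a
    Gaussian elution peak at the target m/z whose area is the condition mean
    perturbed by log-normal scatter of coefficient-of-variation ``cv``.
    """
    if not (0 <= true_loss_fraction <= 1):
        raise ValueError("true_loss_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_control_replicates is None:
        n_control_replicates = n_replicates
    means = {
        "control": control_mean_area,
        treated_label: control_mean_area * (1.0 - true_loss_fraction),
    }
    counts = {"control": n_control_replicates, treated_label: n_replicates}
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv ** 2)))
        mu = -sigma ** 2 / 2.0  # unit-mean log-normal
    else:
        sigma = mu = 0.0

    apex_rt, peak_sigma = 300.0, 5.0
    times = np.arange(250.0, 350.0, 1.0)
    shape = np.exp(-0.5 * ((times - apex_rt) / peak_sigma) ** 2)
    shape /= np.trapezoid(shape, times)  # unit-area profile

    runs: dict[str, list[list[Spectrum]]] = {}
    true_areas: dict[str, list[float]] = {}
    for condition in ("control", treated_label):
        runs[condition] = []
        true_areas[condition] = []
        for replicate in range(counts[condition]):
            factor = float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0
            area = means[condition] * factor
            scans = [
                Spectrum(
                    scan_id=f"{condition}_{replicate}_scan{i}",
                    mz=np.array([target_mz]),
                    intensity=np.array([area * shape[i]]),
                    ms_level=1,
                    retention_time=float(t),
                )
                for i, t in enumerate(times)
            ]
            runs[condition].append(scans)
            true_areas[condition].append(area)
    return QuantDataset(target_mz, runs, true_areas)


# ---------------------------------------------------------------------------
# Fixture bundle


def toy_proteome(
    n_proteins: int = 20,
    seed: int = 0,
    peptides_per_protein: int = 8,
) -> list[tuple[str, str]]:
    """Cys-rich toy proteins yielding tryptic peptides of length 8-15."""
    rng = np.random.default_rng(seed)
    proteins = []
    for p in range(n_proteins):
        parts = ["M"]
        for _ in range(peptides_per_protein):
            length = int(rng.integers(7, 15))
            residues = list(rng.choice(list(_AA_POOL), size=length))
            # one or two cysteines at interior positions
            n_cys = int(rng.integers(1, 3))
            for pos in rng.choice(range(1, length - 1), size=min(n_cys, length - 2),
                                  replace=False):
                residues[pos] = "C"
            residues.append("K" if rng.random() < 0.5 else "R")
            parts.append("".join(residues))
        proteins.append((f"TOY{p + 1:03d}", "".join(parts)))
    return proteins


def write_fasta(proteins: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for accession, sequence in proteins:
            fh.write(f">{accession} synthetic toy protein\n")
            for i in range(0, len(sequence), 60):
                fh.write(sequence[i:i + 60] + "\n")


def planted_peptidoforms(
    proteins: Sequence[tuple[str, str]],
    n: int,
    seed: int,
    mod_names: Sequence[str] = ("palmitoyl", "myristoyl", "stearoyl"),
) -> list[tuple[Peptidoform, int]]:
    """Sample Cys-containing tryptic peptides and acylate one cysteine."""
    from .digestion import DigestParams, digest

    rng = np.random.default_rng(seed)
    candidates: list[str] = []
    seen: set[str] = set()
    for _acc, sequence in proteins:
        for pep in digest(sequence, DigestParams(missed_cleavages=0,
                                                 min_length=7, max_length=20)):
            if "C" in pep.sequence and pep.sequence not in seen:
                seen.add(pep.sequence)
                candidates.append(pep.sequence)
    candidates.sort()
    out: list[tuple[Peptidoform, int]] = []
    for i in range(n):
        sequence = candidates[int(rng.integers(len(candidates)))]
        cys_positions = [k + 1 for k, aa in enumerate(sequence) if aa == "C"]
        site = int(rng.choice(cys_positions))
        mod = registry_lookup(str(rng.choice(list(mod_names))))
        charge = int(rng.integers(2, 4))
        out.append((Peptidoform(sequence, ((site, mod),)), charge))
    return out


def write_fixture_files(
    out_dir: str | Path,
    seed: int = 0,
    n_planted: int = 100,
    n_noise: int = 100,
    n_proteins: int = 20,
) -> dict:
    """Write the full fixture bundle: toy FASTA, planted + noise MS2 spectra
    (MGF and mzML), a quant dataset, and a plain-text manifest.

    Returns the manifest as a dict (scan id -> ground truth for planted
    spectra, plus bundle-level metadata).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    proteins = toy_proteome(n_proteins, seed=seed)
    write_fasta(proteins, out_dir / "toy.fasta")

    planted = planted_peptidoforms(proteins, n_planted, seed=seed + 1)
    spectra: list[Spectrum] = []
    truth: dict[str, str] = {}
    for i, (form, charge) in enumerate(planted):
        spectrum, _ions = simulate_spectrum(SpectrumSimParams(
            peptidoform=form,
            activation="HCD",
            precursor_charge=charge,
            ion_sampling_fraction=0.9,
            noise_peak_count=20,
            mz_jitter_ppm_sigma=3.0,
            seed=int(rng.integers(2 ** 31)),
        ))
        spectrum.scan_id = f"planted_{i:04d}"
        spectra.append(spectrum)
        truth[spectrum.scan_id] = f"{form}/{charge}"

    # noise spectra reuse realistic precursor masses but carry random peaks,
    # exercising the decoy competition rather than the precursor filter
    planted_mzs = np.array([s.precursor_mz for s in spectra])
    for i in range(n_noise):
        n_peaks = int(rng.integers(40, 80))
        mzs = np.sort(rng.uniform(120.0, 1800.0, size=n_peaks))
        intensities = rng.uniform(1.0, 500.0, size=n_peaks)
        precursor = float(rng.choice(planted_mzs))
        spectra.append(Spectrum(
            scan_id=f"noise_{i:04d}",
            mz=mzs,
            intensity=intensities,
            ms_level=2,
            precursor_mz=precursor,
            precursor_charge=int(rng.integers(2, 4)),
            activation="HCD",
            retention_time=600.0,
        ))

    write_mgf(spectra, out_dir / "spectra.mgf")
    write_mzml(spectra, out_dir / "spectra.mzML")

    manifest_lines = [
        f"bundle_version=1",
        f"seed={seed}",
        f"n_proteins={n_proteins}",
        f"n_planted={n_planted}",
        f"n_noise={n_noise}",
    ]
    for scan_id in sorted(truth):
        manifest_lines.append(f"truth.{scan_id}={truth[scan_id]}")
    (out_dir / "manifest.txt").write_text(
        "\n".join(manifest_lines) + "\n", encoding="utf-8"
    )
    return {"seed": seed, "truth": truth, "fasta": str(out_dir / "toy.fasta"),
            "mgf": str(out_dir / "spectra.mgf"),
            "mzml": str(out_dir / "spectra.mzML")}
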