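"""Reading and writing spectral and tabular formats (MGF, mzML, TSV).

Centroid-only contract: profile-mode spectra are rejected with a message
advising centroiding, never silently peak-picked.  Retention times are
seconds everywhere inside the package.
"""

from __future__ import annotations

import base64
import logging
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_mzml",
    "read_spectra",
    "write_annotated_tsv",
]

logger = logging.getLogger(__name__)

_MZML_ACTIVATION = {
    "collision-induced dissociation": "CID",
    "beam-type collision-induced dissociation": "HCD",
    "HCD": "HCD",
    "electron transfer dissociation": "ETD",
    "electron transfer/higher-energy collision dissociation": "EThcD",
}


@dataclass
class Spectrum:
    """A centroided spectrum: peak list plus precursor/activation metadata.

    ``ms_level`` 1 spectra carry no precursor; ``activation`` is one of
    CID/HCD/ETD/EThcD or None when the file does not say.
    """

    scan_id: str
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 2
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    activation: str | None = None
    retention_time: float | None = None  # seconds

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.ms_level >= 2 and self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")

    def __len__(self) -> int:
        return int(self.mz.size)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` records.

    ``PEPMASS``, ``CHARGE`` (both ``2+`` and ``+2`` accepted), ``RTINSECONDS``
    and ``TITLE`` are honored; unsorted peak lists are sorted.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            title = str(params.get("title", f"index={i}"))
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"MGF block {title!r} is missing PEPMASS")
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            rt = params.get("rtinseconds")
            spectra.append(Spectrum(
                scan_id=title,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                ms_level=2,
                precursor_mz=float(pepmass[0]),
                precursor_charge=charge or None,
                activation=params.get("activation"),
                retention_time=float(rt) if rt is not None else None,
            ))
    if not spectra:
        warnings.warn(f"no spectra found in {path}")
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write MS2 spectra to MGF (Matrix Science dialect)."""
    entries = []
    for s in spectra:
        params: dict = {"title": s.scan_id, "pepmass": s.precursor_mz}
        if s.precursor_charge:
            params["charge"] = f"{s.precursor_charge}+"
        if s.retention_time is not None:
            params["rtinseconds"] = f"{s.retention_time:.3f}"
        if s.activation:
            params["activation"] = s.activation
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensity,
            "params": params,
        })
    _mgf.write(entries, str(path), file_mode="w")


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, str]:
    out = {}
    for child in element:
        if _localname(child.tag) == "cvParam":
            out[child.get("name")] = child.get("value", "")
    return out


def _find(element, localname: str):
    for child in element.iter():
        if _localname(child.tag) == localname:
            yield child


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    payload = ""
    for child in bda:
        if _localname(child.tag) == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read an mzML 1.1 file (indexed or plain) into :class:`Spectrum` records.

    MS level, selected-ion m/z and charge, activation (from dissociation CV
    terms) and retention time are extracted.  Binary arrays may be 32- or
    64-bit floats, zlib-compressed or not.  Profile-mode spectra raise with
    advice to centroid first.
    """
    spectra: list[Spectrum] = []
    try:
        context = etree.iterparse(str(path), events=("end",), recover=False)
        for _event, element in context:
            if _localname(element.tag) != "spectrum":
                continue
            params = _cv_params(element)
            scan_id = element.get("id", element.get("index", ""))
            if "profile spectrum" in params:
                raise ValueError(
                    f"spectrum {scan_id!r} is profile-mode; "
                    "centroid the data before reading"
                )
            ms_level = int(params.get("ms level", 2))
            precursor_mz = None
            precursor_charge = None
            activation = None
            for precursor in _find(element, "precursor"):
                for ion in _find(precursor, "selectedIon"):
                    ion_params = _cv_params(ion)
                    if "selected ion m/z" in ion_params:
                        precursor_mz = float(ion_params["selected ion m/z"])
                    if ion_params.get("charge state"):
                        precursor_charge = int(float(ion_params["charge state"]))
                for act in _find(precursor, "activation"):
                    act_params = _cv_params(act)
                    for key, name in _MZML_ACTIVATION.items():
                        if key in act_params:
                            activation = name
                            break
                break
            rt = None
            for scan in _find(element, "scan"):
                scan_params_el = [c for c in scan if _localname(c.tag) == "cvParam"]
                for cv in scan_params_el:
                    if cv.get("name") == "scan start time":
                        value = float(cv.get("value"))
                        unit = cv.get("unitName", "second")
                        rt = value * 60.0 if unit == "minute" else value
                break
            mz_array = np.array([])
            intensity_array = np.array([])
            for bda in _find(element, "binaryDataArray"):
                bda_params = _cv_params(bda)
                if "m/z array" in bda_params:
                    mz_array = _decode_binary_array(bda)
                elif "intensity array" in bda_params:
                    intensity_array = _decode_binary_array(bda)
            spectra.append(Spectrum(
                scan_id=str(scan_id),
                mz=mz_array,
                intensity=intensity_array,
                ms_level=ms_level,
                precursor_mz=precursor_mz,
                precursor_charge=precursor_charge,
                activation=activation,
                retention_time=rt,
            ))
            element.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"corrupted mzML {path}: {exc}") from exc
    if not any(s.ms_level == 2 for s in spectra):
        warnings.warn(f"{path} contains no MS2 spectra")
    return spectra


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Dispatch on extension: .mgf or .mzml/.mzML."""
    path = Path(path)
    if path.suffix.lower() == ".mgf":
        return read_mgf(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    raise ValueError(f"unrecognized spectrum file extension: {path.suffix!r}")


# ---------------------------------------------------------------------------
# Minimal mzML writer (plain, centroided, 64-bit little-endian, uncompressed)

_ACTIVATION_CV = {
    "CID": ('MS:1000133', "collision-induced dissociation"),
    "HCD": ('MS:1000422', "beam-type collision-induced dissociation"),
    "ETD": ('MS:1000598', "electron transfer dissociation"),
    "EThcD": ('MS:1002631', "electron transfer/higher-energy collision dissociation"),
}


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def _cv(accession: str, name: str, value: str = "", extra: str = "") -> str:
    return (f'<cvParam cvRef="MS" accession="{accession}" name="{name}" '
            f'value="{value}"{extra}/>')


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as plain (non-indexed) mzML 1.1.

    Supports the subset this package reads back: centroided MS1/MS2 scans
    with precursor, activation and retention-time metadata.
    """
    lines: list[str] = []
    lines.append('<?xml version="1.0" encoding="utf-8"?>')
    lines.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
    )
    lines.append(
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
    )
    lines.append('<run id="run1">')
    lines.append(f'<spectrumList count="{len(spectra)}">')
    for i, s in enumerate(spectra):
        n = len(s)
        lines.append(
            f'<spectrum index="{i}" id="{s.scan_id}" defaultArrayLength="{n}">'
        )
        lines.append(_cv("MS:1000511", "ms level", str(s.ms_level)))
        lines.append(_cv("MS:1000127", "centroid spectrum"))
        if s.retention_time is not None:
            lines.append("<scanList count=\"1\"><scan>")
            lines.append(_cv(
                "MS:1000016", "scan start time", f"{s.retention_time:.6f}",
                extra=' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"',
            ))
            lines.append("</scan></scanList>")
        if s.ms_level >= 2 and s.precursor_mz is not None:
            lines.append('<precursorList count="1"><precursor>')
            lines.append('<selectedIonList count="1"><selectedIon>')
            lines.append(_cv("MS:1000744", "selected ion m/z", f"{s.precursor_mz:.6f}"))
            if s.precursor_charge:
                lines.append(_cv("MS:1000041", "charge state", str(s.precursor_charge)))
            lines.append("</selectedIon></selectedIonList>")
            lines.append("<activation>")
            acc, name = _ACTIVATION_CV.get(s.activation or "HCD", _ACTIVATION_CV["HCD"])
            lines.append(_cv(acc, name))
            lines.append("</activation>")
            lines.append("</precursor></precursorList>")
        lines.append(f'<binaryDataArrayList count="2">')
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz),
            ("MS:1000515", "intensity array", s.intensity),
        ):
            payload = _encode_array(arr)
            lines.append(f'<binaryDataArray encodedLength="{len(payload)}">')
            lines.append(_cv("MS:1000523", "64-bit float"))
            lines.append(_cv("MS:1000576", "no compression"))
            lines.append(_cv(accession, name))
            lines.append(f"<binary>{payload}</binary>")
            lines.append("</binaryDataArray>")
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines.append("</spectrumList>")
    lines.append("</run>")
    lines.append("</mzML>")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_annotated_tsv(results: Iterable, stream_or_path: TextIO | str | Path) -> None:
    """Write peak-level annotation rows.

    One row per matched peak: scan_id, peptidoform, ion label, theoretical
    m/z, observed m/z, ppm error, intensity.  Rows ordered by (scan, then
    theoretical m/z) so reruns are byte-identical.
    """
    own = isinstance(stream_or_path, (str, Path))
    stream = open(stream_or_path, "w", encoding="utf-8") if own else stream_or_path
    try:
        stream.write(
            "scan_id\tpeptidoform\tion\ttheoretical_mz\tobserved_mz\tppm_error\tintensity\n"
        )
        rows = []
        for result in results:
            for match in result.matches:
                rows.append((
                    result.spectrum_id, str(result.peptidoform),
                    match.fragment.label, match.fragment.mz,
                    match.observed_mz, match.ppm_error, match.observed_intensity,
                ))
        rows.sort(key=lambda r: (r[0], r[3]))
        for scan, pep, label, theo, obs, ppm, inten in rows:
            stream.write(
                f"{scan}\t{pep}\t{label}\t{theo:.5f}\t{obs:.5f}\t{ppm:+.2f}\t{inten:.4f}\n"
            )
    finally:
        if own:
            stream.close()
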