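"""Text notation for peptidoforms.

Grammar (the single user-facing way to write a peptidoform)::

    peptidoform := [nterm-mod "-"] residue+ ["/" charge]
    residue     := AA ["[" mod-name "]"]

Examples: ``IC[palmitoyl]LR/2``, ``GC[palmitoyl]GC[stearoyl]GLK``,
``[acetyl-protein-N-term]-MDSCK``.  Modification names resolve against the
built-in registry (or a user-supplied one).
"""

from __future__ import annotations

from typing import Mapping

from .chem import (
    AMINO_ACID_FORMULAS,
    N_TERM,
    Modification,
    Peptidoform,
    default_registry,
    registry_lookup,
)

__all__ = ["parse_peptidoform", "format_peptidoform", "PeptidoformSyntaxError"]


class PeptidoformSyntaxError(ValueError):
    """Raised when peptidoform text cannot be parsed."""


def parse_peptidoform(
    text: str,
    registry: Mapping[str, Modification] | None = None,
) -> tuple[Peptidoform, int | None]:
    """Parse peptidoform text; returns ``(Peptidoform, charge-or-None)``."""
    reg = default_registry() if registry is None else registry
    if not text or not text.strip():
        raise PeptidoformSyntaxError("empty peptidoform text")
    text = text.strip()

    charge: int | None = None
    if "/" in text:
        body, _, charge_text = text.rpartition("/")
        if not charge_text.isdigit() or int(charge_text) < 1:
            raise PeptidoformSyntaxError(
                f"charge suffix must be a positive integer, got {charge_text!r}"
            )
        charge = int(charge_text)
        text = body

    mods: list[tuple[object, Modification]] = []
    if text.startswith("["):
        end = text.find("]")
        if end == -1 or not text[end + 1 : end + 2] == "-":
            raise PeptidoformSyntaxError(
                "N-terminal modification must be written as '[name]-SEQUENCE'"
            )
        mods.append((N_TERM, _lookup(text[1:end], reg)))
        text = text[end + 2 :]

    sequence: list[str] = []
    i = 0
    while i < len(text):
        aa = text[i]
        if aa not in AMINO_ACID_FORMULAS:
            raise PeptidoformSyntaxError(
                f"unexpected character {aa!r} at position {i + 1}"
            )
        sequence.append(aa)
        i += 1
        if i < len(text) and text[i] == "[":
            end = text.find("]", i)
            if end == -1:
                raise PeptidoformSyntaxError(f"unterminated '[' at position {i + 1}")
            mods.append((len(sequence), _lookup(text[i + 1 : end], reg)))
            i = end + 1
    if not sequence:
        raise PeptidoformSyntaxError("peptidoform contains no residues")

    try:
        peptidoform = Peptidoform("".join(sequence), tuple(mods))
    except ValueError as exc:
        raise PeptidoformSyntaxError(str(exc)) from exc
    return peptidoform, charge


def _lookup(name: str, registry: Mapping[str, Modification]) -> Modification:
    try:
        return registry_lookup(name, registry)
    except KeyError as exc:
        raise PeptidoformSyntaxError(str(exc)) from exc


def format_peptidoform(p: Peptidoform, charge: int | None = None) -> str:
    """Inverse of :func:`parse_peptidoform` (canonical text form)."""
    by_pos = {pos: mod for pos, mod in p.modifications if isinstance(pos, int)}
    nterm = [mod for pos, mod in p.modifications if pos == N_TERM]
    parts = []
    if nterm:
        parts.append(f"[{nterm[0].name}]-")
    for i, aa in enumerate(p.sequence, start=1):
        parts.append(aa)
        if i in by_pos:
            parts.append(f"[{by_pos[i].name}]")
    text = "".join(parts)
    if charge is not None:
        text += f"/{charge}"
    return text
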