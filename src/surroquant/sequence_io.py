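"""Protein sequence input/output and panel validation.

Reads species-tagged protein sequences from FASTA and bundles
target/surrogate protein pairs into a panel definition consumed by the
design pipeline.  The FASTA dialect is deliberately minimal: everything
after ``>`` up to the first whitespace is the identifier, the remainder
of the header line is a free-text description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .constants import NONSTANDARD_RESIDUES, STANDARD_RESIDUES

__all__ = [
    "FastaError",
    "PanelDefinition",
    "ProteinRecord",
    "read_fasta",
    "validate_panel",
    "write_fasta",
]


class FastaError(ValueError):
    """Malformed FASTA input or a sequence that fails residue validation."""


@dataclass(frozen=True)
class ProteinRecord:
    """A species-tagged protein sequence.

    ``species`` is a free-text tag ("human", "bovine", ...) used to keep
    target and surrogate proteomes apart throughout the design pipeline.
    """

    identifier: str
    species: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"record {self.identifier!r} has an empty sequence")


def _validate_residues(record: ProteinRecord, strict: bool) -> list[str]:
    """Return validation messages for non-standard residues.

    In strict mode a message is produced for any character outside the
    20 standard codes.  In lenient mode ambiguity codes (B/J/O/U/X/Z)
    are flagged as rejection messages rather than errors — they are
    never silently assigned a mass.
    """
    messages = []
    for pos, residue in enumerate(record.sequence, start=1):
        if residue in STANDARD_RESIDUES:
            continue
        kind = "ambiguous" if residue in NONSTANDARD_RESIDUES else "invalid"
        if strict or kind == "invalid":
            messages.append(
                f"record {record.identifier!r}: {kind} residue {residue!r} "
                f"at position {pos}"
            )
        else:
            messages.append(
                f"record {record.identifier!r}: ambiguous residue {residue!r} "
                f"at position {pos} (flagged, no mass assigned)"
            )
    return messages


def read_fasta(path: str | Path, species: str, strict: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into species-tagged protein records.

    Sequences are uppercased and whitespace-stripped; entry order is
    preserved.  In strict mode (default) any residue outside the 20
    standard codes raises :class:`FastaError` naming the record and
    position.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    with open(path) as handle:
        # Reject bodies appearing before any header, which SeqIO would skip.
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaError(f"{path}: line 1: expected '>' header, got {first.strip()!r}")
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace(" ", "")
        if not seq:
            raise FastaError(f"{path}: record {entry.id!r} has an empty sequence")
        record = ProteinRecord(
            identifier=entry.id,
            species=species,
            sequence=seq,
            description=entry.description[len(entry.id):].strip(),
        )
        if strict:
            problems = _validate_residues(record, strict=True)
            if problems:
                raise FastaError("; ".join(problems))
        records.append(record)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence bodies at ``width`` columns."""
    with open(path, "w") as handle:
        for record in records:
            header = record.identifier
            if record.description:
                header += f" {record.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(record.sequence), width):
                handle.write(record.sequence[i : i + width] + "\n")


@dataclass
class PanelDefinition:
    """Target/surrogate protein pairs plus the settings used to design them."""

    entries: list[tuple[ProteinRecord, ProteinRecord]]
    settings: dict = field(default_factory=dict)


def validate_panel(panel: PanelDefinition, strict: bool = True) -> list[str]:
    """Diagnose panel problems; an empty list means the panel is well formed.

    Checks that each entry pairs two different species tags and that all
    sequences pass residue validation.  Messages identify the offending
    entry; nothing is raised.
    """
    messages: list[str] = []
    for i, (target, surrogate) in enumerate(panel.entries):
        label = f"entry {i} ({target.identifier}/{surrogate.identifier})"
        if target.species == surrogate.species:
            messages.append(f"{label}: both proteins tagged species {target.species!r}")
        for record in (target, surrogate):
            for msg in _validate_residues(record, strict=strict):
                messages.append(f"{label}: {msg}")
    return messages
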