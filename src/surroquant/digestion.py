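"""In-silico tryptic digestion.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline (P).  Peptides are annotated with 1-based inclusive
positions in the parent protein and their internal missed-cleavage
count, the coordinate convention used on MRM method sheets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .sequence_io import ProteinRecord

__all__ = ["Peptide", "digest", "peptide_index", "export_digest"]


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with its provenance in the parent protein."""

    sequence: str
    parent: str  # parent ProteinRecord identifier
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices *after which* trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    min_len: int = 5,
    max_len: int = 30,
) -> list[Peptide]:
    """Tryptic peptides of ``protein`` with up to ``max_missed`` missed cleavages.

    Returns every peptide bounded by valid cleavage sites (or the protein
    termini) containing 0..max_missed internal cleavage sites, with
    length within [min_len, max_len], ordered by start position then
    missed-cleavage count.  The protein C-terminus always closes a
    peptide regardless of residue identity.
    """
    if max_missed < 0:
        raise ValueError(f"max_missed must be >= 0, got {max_missed}")
    if not 1 <= min_len <= max_len:
        raise ValueError(f"require 1 <= min_len <= max_len, got [{min_len}, {max_len}]")
    seq = protein.sequence
    # Peptide boundaries: position 0, each cleavage point (index after the
    # cleaved residue), and the end of the sequence.
    cuts = [0] + [i + 1 for i in cleavage_sites(seq)] + [len(seq)]
    peptides: list[Peptide] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            start, end = cuts[a], cuts[b]
            if not min_len <= end - start <= max_len:
                continue
            peptides.append(
                Peptide(
                    sequence=seq[start:end],
                    parent=protein.identifier,
                    start=start + 1,
                    end=end,
                    missed_cleavages=b - a - 1,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def peptide_index(
    peptides: Iterable[Peptide],
) -> Mapping[str, list[tuple[str, tuple[int, int]]]]:
    """Map each peptide sequence to every (parent, span) where it occurs.

    Supports proteotypicity checks: a sequence occurring at more than one
    locus is not a unique signature of its parent protein.  Lookup of an
    absent sequence yields an empty list.
    """
    index: dict[str, list[tuple[str, tuple[int, int]]]] = defaultdict(list)
    for pep in peptides:
        index[pep.sequence].append((pep.parent, pep.span))
    return index


def export_digest(peptides: Iterable[Peptide], path: str | Path, sep: str = ",") -> None:
    """Write a digest as delimited text: parent, sequence, start, end, missed_cleavages."""
    frame = pd.DataFrame(
        [
            {
                "parent": p.parent,
                "sequence": p.sequence,
                "start": p.start,
                "end": p.end,
                "missed_cleavages": p.missed_cleavages,
            }
            for p in peptides
        ],
        columns=["parent", "sequence", "start", "end", "missed_cleavages"],
    )
    frame.to_csv(path, sep=sep, index=False)
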