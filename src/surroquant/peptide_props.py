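"""Peptide physicochemical properties.

Monoisotopic mass, precursor m/z at arbitrary positive charge, singly and
multiply charged b/y fragment-ion m/z, and the GRAVY (grand average of
hydropathy) index.  These are the quantities an MRM method sheet reports
for each monitored peptide: precursor ions are conventionally given as
(M + 2H)2+ and product ions as 1+ b/y fragments.

All masses are monoisotopic and unmodified by default; fixed
modifications may be supplied as per-residue mass deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .constants import KYTE_DOOLITTLE, PROTON, RESIDUE_MONO_MASS, WATER_MONO

__all__ = [
    "FragmentIon",
    "PeptideProperties",
    "fragment_mz",
    "gravy",
    "monoisotopic_mass",
    "peptide_properties",
    "precursor_mz",
    "round_half_away",
]


class ResidueError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ResidueError("empty peptide sequence")
    for pos, residue in enumerate(sequence, start=1):
        if residue not in RESIDUE_MONO_MASS:
            raise ResidueError(
                f"non-standard residue {residue!r} at position {pos} "
                f"in {sequence!r}"
            )


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (printed-table convention).

    Python's built-in ``round`` uses banker's rounding; printed m/z and
    hydropathy tables round 0.x5 up, so comparisons against published
    values use this helper.
    """
    factor = 10.0 ** ndigits
    scaled = value * factor
    return math.floor(scaled + 0.5) / factor if scaled >= 0 else math.ceil(scaled - 0.5) / factor


def monoisotopic_mass(
    sequence: str, fixed_mods: Mapping[str, float] | None = None
) -> float:
    """Neutral monoisotopic mass of a peptide in Da.

    Sum of residue monoisotopic masses plus one water.  ``fixed_mods``
    maps residue letters to mass deltas applied at every occurrence
    (e.g. ``{"C": 57.02146}`` for carbamidomethyl cysteine).
    """
    _check_sequence(sequence)
    mass = WATER_MONO + sum(RESIDUE_MONO_MASS[r] for r in sequence)
    if fixed_mods:
        mass += sum(fixed_mods.get(r, 0.0) for r in sequence)
    return mass


def precursor_mz(
    sequence: str, charge: int, fixed_mods: Mapping[str, float] | None = None
) -> float:
    """m/z of the intact peptide at the given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (monoisotopic_mass(sequence, fixed_mods) + charge * PROTON) / charge


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion of a peptide."""

    series: str  # "b" or "y"
    index: int  # number of residues retained in the fragment
    charge: int
    mz: float

    @property
    def annotation(self) -> str:
        """Conventional label such as ``y5`` or ``b3`` (charge implied 1+ unless >1)."""
        label = f"{self.series}{self.index}"
        if self.charge > 1:
            label += f"^{self.charge}"
        return label


def fragment_mz(
    sequence: str,
    series: str,
    index: int,
    charge: int = 1,
    fixed_mods: Mapping[str, float] | None = None,
) -> FragmentIon:
    """m/z of a b- or y-series fragment ion.

    The y(i) ion retains the *i* C-terminal residues plus water; the
    b(i) ion retains the *i* N-terminal residues without water.  Valid
    indices run from 1 to len(sequence) - 1.
    """
    _check_sequence(sequence)
    if series not in ("b", "y"):
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    n = len(sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(
            f"fragment index {index} out of range [1, {n - 1}] for {sequence!r}"
        )
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    mods = fixed_mods or {}
    if series == "y":
        residues = sequence[n - index:]
        neutral = WATER_MONO + sum(RESIDUE_MONO_MASS[r] + mods.get(r, 0.0) for r in residues)
    else:
        residues = sequence[:index]
        neutral = sum(RESIDUE_MONO_MASS[r] + mods.get(r, 0.0) for r in residues)
    return FragmentIon(series, index, charge, (neutral + charge * PROTON) / charge)


def gravy(sequence: str) -> float:
    """GRAVY index: mean Kyte-Doolittle hydropathy over the residues.

    Used as a proxy for reversed-phase retention behaviour when comparing
    an analyte peptide with its surrogate internal-standard peptide.
    """
    _check_sequence(sequence)
    return sum(KYTE_DOOLITTLE[r] for r in sequence) / len(sequence)


@dataclass(frozen=True)
class PeptideProperties:
    """Bundle of the per-peptide quantities reported on a method sheet."""

    sequence: str
    monoisotopic_mass: float
    precursor_mz_by_charge: dict[int, float]
    gravy: float

    @property
    def length(self) -> int:
        return len(self.sequence)


def peptide_properties(
    sequence: str,
    charges: tuple[int, ...] = (2, 3),
    fixed_mods: Mapping[str, float] | None = None,
) -> PeptideProperties:
    """Compute mass, precursor m/z at the requested charges, and GRAVY."""
    mass = monoisotopic_mass(sequence, fixed_mods)
    mz = {z: (mass + z * PROTON) / z for z in charges}
    return PeptideProperties(sequence, mass, mz, gravy(sequence))
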