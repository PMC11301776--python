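"""MRM transition enumeration, isobaric screening and role assignment.

A transition is a (precursor m/z, product m/z) pair monitored on a
triple quadrupole.  For each selected peptide the candidate b/y product
ions are enumerated, screened against the assay background for isobaric
interference at the instrument's quadrupole tolerances, and one
surviving transition is assigned the quantifier role with the next best
serving as qualifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .digestion import Peptide
from .peptide_props import fragment_mz, precursor_mz

__all__ = [
    "ConflictReport",
    "Transition",
    "detect_isobaric_conflicts",
    "enumerate_transitions",
    "export_transition_list",
    "finalize_roles",
    "read_transition_list",
]

ROLE_CANDIDATE = "candidate"
ROLE_QUANTIFIER = "quantifier"
ROLE_QUALIFIER = "qualifier"


@dataclass(frozen=True)
class Transition:
    peptide: Peptide
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    product_annotation: str  # e.g. "y5"
    product_charge: int
    collision_energy: float | None = None  # user-supplied, instrument specific
    role: str = ROLE_CANDIDATE

    @property
    def key(self) -> tuple:
        """Identity of the monitored ion pair, ignoring role/CE metadata."""
        return (
            self.peptide.parent,
            self.peptide.sequence,
            self.precursor_charge,
            self.product_annotation,
            self.product_charge,
        )


def enumerate_transitions(
    peptide: Peptide,
    precursor_charges: Iterable[int] = (2,),
    series: Iterable[str] = ("y",),
    min_index: int = 1,
    max_index: int | None = None,
    product_charges: Iterable[int] = (1,),
) -> list[Transition]:
    """All candidate transitions for a peptide, in deterministic order
    (precursor charge, series, fragment index, product charge)."""
    n = len(peptide.sequence)
    if max_index is None:
        max_index = n - 1
    if not 1 <= min_index <= max_index <= n - 1:
        raise ValueError(
            f"fragment index bounds [{min_index}, {max_index}] outside [1, {n - 1}]"
        )
    out: list[Transition] = []
    for z in sorted(set(precursor_charges)):
        pre = precursor_mz(peptide.sequence, z)
        for ser in sorted(set(series)):
            for idx in range(min_index, max_index + 1):
                for pz in sorted(set(product_charges)):
                    frag = fragment_mz(peptide.sequence, ser, idx, pz)
                    out.append(
                        Transition(
                            peptide=peptide,
                            precursor_mz=pre,
                            precursor_charge=z,
                            product_mz=frag.mz,
                            product_annotation=frag.annotation,
                            product_charge=pz,
                        )
                    )
    return out


@dataclass(frozen=True)
class ConflictReport:
    """An isobaric interference: a background ion falls inside both
    quadrupole windows of a monitored transition."""

    transition: Transition
    interferer_peptide: Peptide
    interferer_annotation: str
    precursor_delta: float
    product_delta: float


def detect_isobaric_conflicts(
    candidates: Sequence[Transition],
    background: Sequence[Peptide],
    precursor_tol: float = 0.7,
    product_tol: float = 0.7,
) -> list[ConflictReport]:
    """Screen candidate transitions against a digested background.

    A candidate conflicts iff some background peptide other than its own
    has a precursor (at the candidate's precursor charge) within
    ``precursor_tol`` AND any b/y product ion (at the candidate's product
    charge) within ``product_tol``.  Every conflict is reported; nothing
    is suppressed.  Default tolerances reflect unit-resolution quadrupole
    windows (0.7 Da FWHM).
    """
    if precursor_tol <= 0 or product_tol <= 0:
        raise ValueError("tolerances must be positive")
    reports: list[ConflictReport] = []
    for cand in candidates:
        own = (cand.peptide.parent, cand.peptide.span, cand.peptide.sequence)
        for bg in background:
            if (bg.parent, bg.span, bg.sequence) == own:
                continue
            pre_delta = precursor_mz(bg.sequence, cand.precursor_charge) - cand.precursor_mz
            if abs(pre_delta) > precursor_tol:
                continue
            n = len(bg.sequence)
            for ser in ("b", "y"):
                for idx in range(1, n):
                    frag = fragment_mz(bg.sequence, ser, idx, cand.product_charge)
                    prod_delta = frag.mz - cand.product_mz
                    if abs(prod_delta) <= product_tol:
                        reports.append(
                            ConflictReport(
                                transition=cand,
                                interferer_peptide=bg,
                                interferer_annotation=frag.annotation,
                                precursor_delta=pre_delta,
                                product_delta=prod_delta,
                            )
                        )
    return reports


def _default_rank_key(t: Transition) -> tuple:
    # Prefer y-series, then longer fragments, then lower product charge;
    # deterministic tie-break by m/z.
    idx = int("".join(ch for ch in t.product_annotation.split("^")[0][1:]))
    return (t.product_annotation[0] != "y", -idx, t.product_charge, t.product_mz)


def finalize_roles(
    candidates: Sequence[Transition],
    n_qualifiers: int = 3,
    ranking: Callable[[Transition], tuple] | None = None,
    peptides: Sequence[Peptide] | None = None,
) -> tuple[list[Transition], list[Peptide]]:
    """Assign quantifier/qualifier roles per peptide.

    The top-ranked candidate of each peptide becomes the quantifier and
    the next ``n_qualifiers`` become qualifiers.  When ``peptides`` lists
    the peptides that were supposed to be covered, any of them left with
    zero (unconflicted) candidates is returned as a design failure —
    reported, not raised.
    """
    key = ranking or _default_rank_key
    by_peptide: dict[tuple, list[Transition]] = {}
    order: list[tuple] = []
    for t in candidates:
        pk = (t.peptide.parent, t.peptide.span, t.peptide.sequence)
        if pk not in by_peptide:
            by_peptide[pk] = []
            order.append(pk)
        by_peptide[pk].append(t)
    finalized: list[Transition] = []
    for pk in order:
        group = sorted(by_peptide[pk], key=key)
        finalized.append(replace(group[0], role=ROLE_QUANTIFIER))
        finalized.extend(replace(t, role=ROLE_QUALIFIER) for t in group[1 : 1 + n_qualifiers])
    failures = [
        p
        for p in (peptides or [])
        if (p.parent, p.span, p.sequence) not in by_peptide
    ]
    return finalized, failures


COLUMNS = [
    "protein",
    "peptide",
    "precursor_mz",
    "precursor_charge",
    "product_mz",
    "product_annotation",
    "product_charge",
    "collision_energy",
    "role",
]


def export_transition_list(transitions: Sequence[Transition], path: str | Path) -> None:
    """Write the transition list as CSV with m/z at 4 decimal places."""
    rows = [
        {
            "protein": t.peptide.parent,
            "peptide": t.peptide.sequence,
            "precursor_mz": f"{t.precursor_mz:.4f}",
            "precursor_charge": t.precursor_charge,
            "product_mz": f"{t.product_mz:.4f}",
            "product_annotation": t.product_annotation,
            "product_charge": t.product_charge,
            "collision_energy": "" if t.collision_energy is None else t.collision_energy,
            "role": t.role,
        }
        for t in transitions
    ]
    try:
        pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write transition list to {path}: {exc}") from exc


def read_transition_list(path: str | Path) -> pd.DataFrame:
    """Read a transition-list CSV written by :func:`export_transition_list`."""
    try:
        frame = pd.read_csv(path, dtype={"collision_energy": float})
    except OSError as exc:
        raise OSError(f"cannot read transition list from {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing transition-list columns {missing}")
    return frame[COLUMNS]
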