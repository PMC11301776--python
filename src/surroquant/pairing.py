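"""Surrogate internal-standard peptide pairing.

For each proteotypic peptide of a target protein (e.g. human), find the
homology-anchored peptide of the surrogate-species protein (e.g. bovine)
that can serve as its co-digested internal standard.  Candidate pairs
must be species specific, come from corresponding positions of the
globally aligned protein sequences, be free of isobaric interference
within the assay, and be as similar as possible in length and
hydrophobicity (a proxy for retention time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .digestion import Peptide, digest, peptide_index
from .peptide_props import gravy
from .sequence_io import PanelDefinition, ProteinRecord

__all__ = [
    "AlignmentResult",
    "DesignConfig",
    "DesignReport",
    "EntryDesign",
    "SpecificityVerdict",
    "SurrogatePair",
    "align_global",
    "check_species_specificity",
    "design_panel",
    "map_homologous_peptides",
    "score_pair",
]

# Exclusion flag vocabulary.
NOT_SPECIES_SPECIFIC = "not_species_specific"
ISOBARIC_CONFLICT = "isobaric_conflict"
LOW_HOMOLOGY = "low_homology"


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise protein alignment with column bookkeeping.

    ``column_map[i]`` gives, for the i-th (0-based) residue of sequence
    ``a``, the 0-based position of its aligned partner in ``b``, or None
    when it sits opposite a gap.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identical_positions: int
    similar_positions: int
    column_map: tuple[int | None, ...]

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)

    @property
    def identity_fraction(self) -> float:
        return self.identical_positions / self.alignment_length

    @property
    def sequence_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def sequence_b(self) -> str:
        return self.aligned_b.replace("-", "")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython convention: open_gap_score is the score of the first gap
    # position, so a gap of length L costs gap_open + (L-1)*gap_extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_global(
    a: str,
    b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global (end-gap-penalized) alignment of two protein sequences.

    Similar positions are aligned, non-identical residue pairs with a
    positive substitution score.  Ties between co-optimal alignments are
    broken deterministically by the aligner's enumeration order.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    matrix = aligner.substitution_matrix
    identical = similar = 0
    column_map: list[int | None] = []
    pos_b = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            if ca == cb:
                identical += 1
            elif matrix[ca, cb] > 0:
                similar += 1
            column_map.append(pos_b)
        elif ca != "-":
            column_map.append(None)
        if cb != "-":
            pos_b += 1
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identical_positions=identical,
        similar_positions=similar,
        column_map=tuple(column_map),
    )


@dataclass(frozen=True)
class SpecificityVerdict:
    """Outcome of the species-specificity / proteotypicity screen."""

    peptide: Peptide
    species_specific: bool
    own_hits: tuple[tuple[str, tuple[int, int]], ...]
    other_hits: tuple[tuple[str, tuple[int, int]], ...]


def check_species_specificity(
    peptide: Peptide,
    own_digest_index: Mapping[str, list],
    other_digest_index: Mapping[str, list],
) -> SpecificityVerdict:
    """A peptide is usable iff it is proteotypic in its own proteome
    (exactly one occurrence) and absent from the other species' digest."""
    own = tuple(own_digest_index.get(peptide.sequence, ()))
    other = tuple(other_digest_index.get(peptide.sequence, ()))
    return SpecificityVerdict(
        peptide=peptide,
        species_specific=(len(own) == 1 and len(other) == 0),
        own_hits=own,
        other_hits=other,
    )


@dataclass(frozen=True)
class SurrogatePair:
    """A target peptide matched to a candidate surrogate-IS peptide."""

    target: Peptide
    surrogate: Peptide
    span_overlap_fraction: float
    length_delta: int  # len(surrogate) - len(target)
    gravy_delta: float  # absolute GRAVY difference
    substitution_count: int  # differing columns in the peptide-level alignment
    exclusion_flags: frozenset[str] = frozenset()
    score: float = math.inf

    def with_flags(self, *flags: str) -> "SurrogatePair":
        return replace(self, exclusion_flags=self.exclusion_flags | set(flags))


def _peptide_substitutions(a: str, b: str) -> int:
    """Differing columns (mismatches plus gap columns) after aligning the
    two peptide sequences themselves."""
    if a == b:
        return 0
    result = align_global(a, b)
    return sum(ca != cb for ca, cb in zip(result.aligned_a, result.aligned_b))


def map_homologous_peptides(
    target_digest: Sequence[Peptide],
    surrogate_digest: Sequence[Peptide],
    alignment: AlignmentResult,
    overlap_threshold: float = 0.5,
    keep_below_threshold: bool = False,
) -> list[SurrogatePair]:
    """Candidate pairs anchored at corresponding protein positions.

    For every target peptide, each surrogate peptide whose span covers at
    least ``overlap_threshold`` of the target's aligned positions is
    emitted as an unscored candidate.  With ``keep_below_threshold`` the
    sub-threshold pairs (overlap > 0) are also returned, flagged
    ``low_homology``, so the design report can show why they were
    rejected.
    """
    _parent_check(target_digest, alignment.sequence_a)
    _parent_check(surrogate_digest, alignment.sequence_b)
    pairs: list[SurrogatePair] = []
    for t in target_digest:
        # Aligned partner positions (0-based in b) of the target span.
        partners = [
            alignment.column_map[i] for i in range(t.start - 1, t.end)
        ]
        for s in surrogate_digest:
            lo, hi = s.start - 1, s.end - 1
            covered = sum(1 for p in partners if p is not None and lo <= p <= hi)
            frac = covered / len(t.sequence)
            if frac <= 0.0:
                continue
            if frac < overlap_threshold and not keep_below_threshold:
                continue
            pair = SurrogatePair(
                target=t,
                surrogate=s,
                span_overlap_fraction=frac,
                length_delta=len(s.sequence) - len(t.sequence),
                gravy_delta=abs(gravy(s.sequence) - gravy(t.sequence)),
                substitution_count=_peptide_substitutions(t.sequence, s.sequence),
            )
            if frac < overlap_threshold:
                pair = pair.with_flags(LOW_HOMOLOGY)
            pairs.append(pair)
    return pairs


def _parent_check(digest_peptides: Sequence[Peptide], sequence: str) -> str:
    """Verify peptide spans are consistent with ``sequence``; returns it."""
    for p in digest_peptides:
        if sequence[p.start - 1 : p.end] != p.sequence:
            raise ValueError(
                f"peptide {p.sequence!r} at {p.start}-{p.end} does not match "
                "the aligned protein sequence"
            )
    return sequence


DEFAULT_WEIGHTS = {"w_len": 1.0, "w_gravy": 1.0, "w_sub": 0.25}


def score_pair(pair: SurrogatePair, weights: Mapping[str, float] | None = None) -> SurrogatePair:
    """Similarity score (lower is better) over length, GRAVY and substitutions.

    score = w_len*|length_delta| + w_gravy*gravy_delta + w_sub*substitution_count
    """
    if pair.exclusion_flags:
        raise ValueError(
            f"cannot score an excluded pair (flags: {sorted(pair.exclusion_flags)})"
        )
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    score = (
        w["w_len"] * abs(pair.length_delta)
        + w["w_gravy"] * pair.gravy_delta
        + w["w_sub"] * pair.substitution_count
    )
    return replace(pair, score=score)


@dataclass
class DesignConfig:
    """Settings for the surrogate-pair design pipeline."""

    max_missed: int = 0
    min_len: int = 5
    max_len: int = 30
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    overlap_threshold: float = 0.5
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    precursor_charges: tuple[int, ...] = (2,)
    product_charges: tuple[int, ...] = (1,)
    series: tuple[str, ...] = ("y",)
    precursor_tol: float = 0.7
    product_tol: float = 0.7
    n_qualifiers: int = 3
    # Optional hook implementing an empirical instrument-response ranking;
    # receives the candidate list and returns it reordered (default no-op).
    response_rank_hook: Callable[[list], list] | None = None


@dataclass
class EntryDesign:
    """Design outcome for one target/surrogate protein pair."""

    target: ProteinRecord
    surrogate: ProteinRecord
    alignment: AlignmentResult
    ranked: dict[str, list[SurrogatePair]]  # target peptide sequence -> ranked pairs
    excluded: list[SurrogatePair]


@dataclass
class DesignReport:
    entries: list[EntryDesign]

    def all_pairs(self) -> list[SurrogatePair]:
        return [p for e in self.entries for pairs in e.ranked.values() for p in pairs]

    def best_pairs(self) -> list[SurrogatePair]:
        """The top-ranked surviving pair for each target peptide."""
        return [pairs[0] for e in self.entries for pairs in e.ranked.values() if pairs]


def design_panel(panel: PanelDefinition, config: DesignConfig | None = None) -> DesignReport:
    """Run the full pair-design pipeline over a validated panel.

    digest both species -> proteome-wide specificity screens -> homology
    mapping on the global protein alignment -> isobaric screening of the
    candidate transitions -> similarity scoring and ranking.  Every
    excluded candidate is retained in the report with its flags; output
    is deterministic for fixed inputs and config.
    """
    from .transitions import detect_isobaric_conflicts, enumerate_transitions

    config = config or DesignConfig()
    digests: dict[str, list[Peptide]] = {}
    species_peptides: dict[str, list[Peptide]] = {}
    seen: set[tuple[str, str]] = set()
    for target, surrogate in panel.entries:
        for rec in (target, surrogate):
            if rec.identifier not in digests:
                digests[rec.identifier] = digest(
                    rec, config.max_missed, config.min_len, config.max_len
                )
            if (rec.species, rec.identifier) not in seen:
                seen.add((rec.species, rec.identifier))
                species_peptides.setdefault(rec.species, []).extend(digests[rec.identifier])
    indexes = {sp: peptide_index(peps) for sp, peps in species_peptides.items()}
    background = [p for peps in species_peptides.values() for p in peps]

    entries: list[EntryDesign] = []
    for target, surrogate in panel.entries:
        alignment = align_global(
            target.sequence,
            surrogate.sequence,
            config.substitution_matrix,
            config.gap_open,
            config.gap_extend,
        )
        candidates = map_homologous_peptides(
            digests[target.identifier],
            digests[surrogate.identifier],
            alignment,
            overlap_threshold=config.overlap_threshold,
            keep_below_threshold=True,
        )
        flagged: list[SurrogatePair] = []
        for pair in candidates:
            t_verdict = check_species_specificity(
                pair.target, indexes[target.species], indexes[surrogate.species]
            )
            s_verdict = check_species_specificity(
                pair.surrogate, indexes[surrogate.species], indexes[target.species]
            )
            if not (t_verdict.species_specific and s_verdict.species_specific):
                pair = pair.with_flags(NOT_SPECIES_SPECIFIC)
            if not pair.exclusion_flags and _has_isobaric_exclusion(
                pair, background, config, enumerate_transitions, detect_isobaric_conflicts
            ):
                pair = pair.with_flags(ISOBARIC_CONFLICT)
            flagged.append(pair)
        ranked: dict[str, list[SurrogatePair]] = {}
        excluded = [p for p in flagged if p.exclusion_flags]
        survivors = [score_pair(p, config.weights) for p in flagged if not p.exclusion_flags]
        for t in digests[target.identifier]:
            mine = [p for p in survivors if p.target == t]
            mine.sort(key=lambda p: (p.score, p.substitution_count, p.surrogate.start))
            if mine:
                ranked[t.sequence] = mine
        entries.append(EntryDesign(target, surrogate, alignment, ranked, excluded))
    return DesignReport(entries)


def _has_isobaric_exclusion(pair, background, config, enumerate_transitions, detect) -> bool:
    """True when either peptide of the pair has no interference-free transition."""
    for pep in (pair.target, pair.surrogate):
        cands = enumerate_transitions(
            pep,
            precursor_charges=config.precursor_charges,
            series=config.series,
            product_charges=config.product_charges,
        )
        conflicts = detect(
            cands, background, config.precursor_tol, config.product_tol
        )
        conflicted = {id(c.transition) for c in conflicts}
        if all(id(c) in conflicted for c in cands):
            return True
    return False
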