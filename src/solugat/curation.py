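"""Homology separation of sequence datasets.

Redundancy reduction proceeds greedily in input order: the first sequence
initializes the library; each subsequent sequence is admitted only if its
global (Needleman-Wunsch) percent identity against every already-admitted
sequence stays below a cutoff (30% by default).  A cross-dataset variant
filters a test set against a fixed reference library.

Scoring is fixed and documented: BLOSUM62 substitution scores with affine
gaps (-10 for the first gap column, -1 for each further column); identity is
matched columns divided by the full alignment length including gap columns
(an alternative denominator, the shorter sequence length, is selectable).
Alignment-significance (E-value) statistics are not computed internally; an
optional user-supplied E-value table can be combined with the identity rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_CUTOFF = 30.0
EVALUE_CUTOFF = 1e-6


@dataclass
class IdentityResult:
    identity_pct: float
    alignment_length: int
    matches: int


@dataclass
class Rejection:
    id: str
    reason: str
    closest_match_id: str
    identity_pct: float


@dataclass
class LibraryState:
    """Outcome of a homology filter: admitted sequences and rejections."""

    admitted: list[tuple[str, str]] = field(default_factory=list)
    rejected: list[Rejection] = field(default_factory=list)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def global_identity(seq_a: str, seq_b: str,
                    denominator: str = "alignment") -> IdentityResult:
    """Global percent identity between two sequences.

    ``denominator`` selects what the match count is divided by:
    ``"alignment"`` (default) uses the full alignment length including gap
    columns; ``"shorter"`` uses the shorter sequence length.  When several
    alignments are optimal, the first reported one is used (deterministic).
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    matches = int(counts.identities)
    length = int(alignment.length)
    if denominator == "alignment":
        denom = length
    elif denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return IdentityResult(identity_pct=100.0 * matches / denom,
                          alignment_length=length, matches=matches)


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Optimal global alignment score under the module's fixed scoring."""
    return float(_ALIGNER.score(seq_a, seq_b))


def _check_ids(sequences) -> None:
    seen = set()
    for sid, _ in sequences:
        if sid in seen:
            raise ValueError(f"duplicate sequence id {sid!r}")
        seen.add(sid)


def _max_identity(seq: str, library, denominator: str):
    """Highest identity of ``seq`` against a list of (id, seq) pairs."""
    best_id, best = "", -1.0
    for ref_id, ref_seq in library:
        result = global_identity(seq, ref_seq, denominator=denominator)
        if result.identity_pct > best:
            best, best_id = result.identity_pct, ref_id
    return best_id, best


def greedy_homology_filter(sequences,
                           identity_cutoff_pct: float = DEFAULT_IDENTITY_CUTOFF,
                           denominator: str = "alignment",
                           evalues: dict | None = None,
                           evalue_rule: str | None = None) -> LibraryState:
    """Greedy order-dependent redundancy reduction.

    ``sequences`` is an ordered list of ``(id, sequence)`` pairs.  The first
    sequence is always admitted; each later sequence is admitted iff its
    maximum identity against all currently admitted sequences is below the
    cutoff.  Results depend on input order by construction.

    ``evalues`` optionally maps ``(query_id, library_id)`` to an externally
    computed E-value; with ``evalue_rule="corrected"`` a significant hit
    (E-value <= 1e-6) also rejects, with ``evalue_rule="literal"`` admission
    additionally requires a significant hit against some admitted sequence.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("empty input")
    _check_ids(sequences)
    if evalue_rule not in (None, "literal", "corrected"):
        raise ValueError(f"unknown evalue_rule {evalue_rule!r}")
    if evalue_rule and evalues is None:
        raise ValueError("evalue_rule requires an evalues table")

    state = LibraryState()
    for sid, seq in sequences:
        if not seq:
            raise ValueError(f"sequence {sid!r} is empty")
        if not state.admitted:
            state.admitted.append((sid, seq))
            continue
        closest, identity = _max_identity(seq, state.admitted, denominator)
        admit = identity < identity_cutoff_pct
        reason = f"identity {identity:.1f}% >= cutoff vs {closest}"
        if evalue_rule:
            hits = [evalues.get((sid, lib_id), float("inf"))
                    for lib_id, _ in state.admitted]
            significant = min(hits) <= EVALUE_CUTOFF
            if evalue_rule == "corrected" and significant:
                admit = False
                reason = f"significant E-value hit vs library ({min(hits):.2g})"
            elif evalue_rule == "literal" and not significant:
                admit = False
                reason = "no significant E-value hit (literal rule)"
        if admit:
            state.admitted.append((sid, seq))
        else:
            state.rejected.append(Rejection(sid, reason, closest, identity))
            logger.info("rejected %s: %s", sid, reason)
    return state


def cross_dataset_filter(test_sequences, reference_library,
                         identity_cutoff_pct: float = DEFAULT_IDENTITY_CUTOFF,
                         denominator: str = "alignment") -> LibraryState:
    """Keep a test sequence iff its maximum identity against every reference
    sequence is below the cutoff."""
    test_sequences = list(test_sequences)
    reference_library = list(reference_library)
    if not test_sequences or not reference_library:
        raise ValueError("both sequence sets must be non-empty")
    _check_ids(test_sequences)
    state = LibraryState()
    for sid, seq in test_sequences:
        if not seq:
            raise ValueError(f"sequence {sid!r} is empty")
        closest, identity = _max_identity(seq, reference_library, denominator)
        if identity < identity_cutoff_pct:
            state.admitted.append((sid, seq))
        else:
            state.rejected.append(Rejection(
                sid, f"identity {identity:.1f}% >= cutoff vs reference "
                     f"{closest}", closest, identity))
    return state
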