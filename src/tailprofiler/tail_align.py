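"""Local alignment of inserts to extended hairpins and tail calling.

Each insert is aligned locally (affine gap penalties) against every hairpin
in the targeted reference set; the single best alignment is chosen by six
ordered criteria — maximum matched bases, minimum mismatches, minimum gap
openings in query, minimum gap openings in target, minimum gapped bases in
query, minimum gapped bases in target — with residual ties broken by
lexicographically smallest hairpin id, then the 3'-most target span.  All
unaligned bases at the 3' end of the chosen local alignment are called as
the non-templated addition (NTA).

Because local alignment greedily absorbs tail bases that happen to match
the reference (a U tail over a templated A/U-rich region), an explicit
rescue pass re-examines the maximal A/U-only suffix of the read: from the
first position in its aligned portion where the read disagrees with the
reference, that base and everything 3' of it are reclassified as
non-templated.  A read whose pure-A/U suffix matches the reference
perfectly stays templated (tail rates are therefore conservative).

The alignment engine is Bio.Align.PairwiseAligner in local mode; a gap of
length k scores ``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from itertools import islice
from typing import Iterable, Sequence

from Bio import Align

from .refprep import HairpinReference, canonicalize

_AU_SUFFIX = re.compile(r"[AT]+$")


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet for tail reporting."""
    return seq.replace("T", "U")


@dataclass(frozen=True)
class AlignScoring:
    """Affine local-alignment scoring; gap(k) = gap_open + (k-1)*gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignScoring()


@dataclass(frozen=True)
class CandidateAlignment:
    """One local alignment of an insert against one hairpin."""

    hairpin_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]  # ((t0,t1),(q0,q1))
    matched: int
    mismatched: int
    q_gap_count: int
    t_gap_count: int
    q_gap_bases: int
    t_gap_bases: int
    score: float

    @property
    def identity(self) -> float:
        total = self.matched + self.mismatched
        return self.matched / total if total else 0.0

    @property
    def selection_key(self) -> tuple:
        """Ordered tie-break tuple; smaller is better."""
        return (
            -self.matched,
            self.mismatched,
            self.q_gap_count,
            self.t_gap_count,
            self.q_gap_bases,
            self.t_gap_bases,
            self.hairpin_id,
            -self.target_span[1],
            -self.target_span[0],
        )


@dataclass(frozen=True)
class TailCall:
    """Per-read outcome: templated 3' end and non-templated suffix.

    ``templated_end`` / ``templated_read_end`` are 0-based indices of the
    last templated base on the extended hairpin / on the insert.  ``nta``
    is reported in the RNA alphabet (U, not T).
    """

    read_id: str
    hairpin_id: str
    templated_end: int
    templated_read_end: int
    nta: str
    rescued: bool = False
    alignment: CandidateAlignment | None = field(default=None, compare=False)


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _candidate_from_alignment(
    aln, hairpin_id: str, target_seq: str, query_seq: str
) -> CandidateAlignment | None:
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks)
    )
    matched = mismatched = 0
    for (t0, t1), (q0, q1) in blocks:
        for ti, qi in zip(range(t0, t1), range(q0, q1)):
            if target_seq[ti] == query_seq[qi]:
                matched += 1
            else:
                mismatched += 1
    q_gap_count = t_gap_count = q_gap_bases = t_gap_bases = 0
    for ((pt0, pt1), (pq0, pq1)), ((t0, t1), (q0, q1)) in zip(blocks, blocks[1:]):
        dq = q0 - pq1
        dt = t0 - pt1
        if dq > 0:  # unaligned query bases: insertion in query
            q_gap_count += 1
            q_gap_bases += dq
        if dt > 0:  # unaligned target bases: deletion from query
            t_gap_count += 1
            t_gap_bases += dt
    return CandidateAlignment(
        hairpin_id=hairpin_id,
        query_span=(blocks[0][1][0], blocks[-1][1][1]),
        target_span=(blocks[0][0][0], blocks[-1][0][1]),
        blocks=blocks,
        matched=matched,
        mismatched=mismatched,
        q_gap_count=q_gap_count,
        t_gap_count=t_gap_count,
        q_gap_bases=q_gap_bases,
        t_gap_bases=t_gap_bases,
        score=float(aln.score),
    )


def align_local(
    insert: str,
    reference: HairpinReference,
    scoring: AlignScoring = DEFAULT_SCORING,
    min_identity: float = 0.70,
    max_co_optimal: int = 16,
) -> list[CandidateAlignment]:
    """All maximal-scoring local alignments of ``insert`` to one hairpin.

    Co-optimal alternatives (same optimal score, different path or
    endpoints) are enumerated up to ``max_co_optimal``; candidates below
    ``min_identity`` (matched / aligned pairs) are discarded.
    """
    insert = canonicalize(insert)
    alns = _make_aligner(scoring).align(reference.sequence, insert)
    try:
        if alns.score <= 0:
            return []
    except (AttributeError, IndexError):  # pragma: no cover
        return []
    out = []
    seen = set()
    for aln in islice(alns, max_co_optimal):
        cand = _candidate_from_alignment(aln, reference.hairpin_id, reference.sequence, insert)
        if cand is None or cand.identity < min_identity:
            continue
        key = (cand.blocks,)
        if key in seen:
            continue
        seen.add(key)
        out.append(cand)
    return out


def align_to_references(
    insert: str,
    references: Iterable[HairpinReference],
    scoring: AlignScoring = DEFAULT_SCORING,
    min_identity: float = 0.70,
) -> list[CandidateAlignment]:
    """Candidates pooled over every hairpin in the reference set."""
    out: list[CandidateAlignment] = []
    for ref in references:
        out.extend(align_local(insert, ref, scoring, min_identity))
    return out


def select_best_alignment(
    candidates: Sequence[CandidateAlignment],
) -> CandidateAlignment | None:
    """Pick the single best candidate by the six ordered criteria.

    Residual ties after the six criteria go to the lexicographically
    smallest hairpin id, then the 3'-most target span, making the choice a
    total order (invariant under input permutation).
    """
    if not candidates:
        return None
    return min(candidates, key=lambda c: c.selection_key)


def call_nta(best: CandidateAlignment, insert: str, read_id: str = "") -> TailCall:
    """Call the 3'-unaligned insert suffix as the non-templated addition."""
    insert = canonicalize(insert)
    q_end = best.query_span[1]
    return TailCall(
        read_id=read_id,
        hairpin_id=best.hairpin_id,
        templated_end=best.target_span[1] - 1,
        templated_read_end=q_end - 1,
        nta=to_rna(insert[q_end:]),
        rescued=False,
        alignment=best,
    )


def _query_column_map(aln: CandidateAlignment) -> dict[int, int | None]:
    """Map each aligned-span query index to its target index, or None for a
    query insertion (no target base)."""
    cols: dict[int, int | None] = {}
    prev_q_end = None
    for (t0, t1), (q0, q1) in aln.blocks:
        if prev_q_end is not None:
            for qi in range(prev_q_end, q0):
                cols[qi] = None
        for ti, qi in zip(range(t0, t1), range(q0, q1)):
            cols[qi] = ti
        prev_q_end = q1
    return cols


def rescue_au_suffix(call: TailCall, insert: str, reference: HairpinReference) -> TailCall:
    """Reclassify a reference-matching A/U-rich read suffix as tail bases.

    The re-examination region is the maximal suffix of the insert composed
    only of A/U.  Its aligned (templated) portion is scanned 5'->3'; at the
    first position disagreeing with the reference (a query insertion counts
    as a disagreement), that base and all bases 3' of it become
    non-templated.  Idempotent; never lengthens the templated region.
    """
    if call.alignment is None:
        raise ValueError("rescue requires a TailCall carrying its alignment")
    insert = canonicalize(insert)
    m = _AU_SUFFIX.search(insert)
    if m is None:
        return call
    region_start = m.start()
    cols = _query_column_map(call.alignment)
    mismatch_q = None
    for qi in range(max(region_start, call.alignment.query_span[0]), call.templated_read_end + 1):
        ti = cols.get(qi)
        if ti is None or insert[qi] != reference.sequence[ti]:
            mismatch_q = qi
            break
    if mismatch_q is None:
        return call
    retained_targets = [
        ti
        for qi, ti in cols.items()
        if ti is not None and qi < mismatch_q and qi <= call.templated_read_end
    ]
    new_templated_end = (
        max(retained_targets) if retained_targets else call.alignment.target_span[0] - 1
    )
    return replace(
        call,
        templated_end=new_templated_end,
        templated_read_end=mismatch_q - 1,
        nta=to_rna(insert[mismatch_q:]),
        rescued=True,
    )


def call_read(
    insert: str,
    references: Sequence[HairpinReference],
    scoring: AlignScoring = DEFAULT_SCORING,
    min_identity: float = 0.70,
    read_id: str = "",
    rescue: bool = True,
) -> TailCall | None:
    """Full per-read pipeline: align, select, call NTA, rescue.

    Returns None when no alignment passes the identity filter.
    """
    best = select_best_alignment(align_to_references(insert, references, scoring, min_identity))
    if best is None:
        return None
    call = call_nta(best, insert, read_id=read_id)
    if rescue:
        ref_by_id = {r.hairpin_id: r for r in references}
        call = rescue_au_suffix(call, insert, ref_by_id[best.hairpin_id])
    return call
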