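"""Reference 3'-end determination and per-read trimming/tail annotation.

The zero point for trimming lengths is learned per hairpin from the control
sample: the modal 3' end of the templated portions of its reads (ties
toward the 3'-most position).  Hairpins whose learned end sits more than
3 nt from the annotated mature-3p 3' end are excluded as likely artifacts.

Per read, trimming length = reference end − templated end (positive =
trimmed, negative = extended into the genomic flank); the U-tail length is
the tail length when the non-templated addition is pure U, and 0 for any
mixed-composition tail.  Read classes: ``Trimmed`` (trim > 0), ``Intact``
(trim = 0, no tail), ``Mono-U`` (trim = 0, tail exactly one U), ``Other``
(everything else, including extended reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .tail_align import TailCall

CLASS_INTACT = "Intact"
CLASS_MONO_U = "Mono-U"
CLASS_TRIMMED = "Trimmed"
CLASS_OTHER = "Other"

READ_CLASSES = (CLASS_INTACT, CLASS_MONO_U, CLASS_TRIMMED, CLASS_OTHER)


@dataclass(frozen=True)
class EndAnnotation:
    hairpin_id: str
    reference_end: int
    excluded: bool = False
    offset_from_mature: int | None = None


@dataclass(frozen=True)
class AnnotatedRead:
    read_id: str
    hairpin_id: str
    trim_len: int
    utail_len: int
    tail_seq: str
    read_class: str


def reference_end_position(
    control_calls: Sequence[TailCall],
    mature_3p_end: int | None = None,
    max_mature_offset: int = 3,
) -> EndAnnotation:
    """Modal templated 3' end of the control reads for one hairpin.

    Ties go to the larger (more 3') position.  When the mature-3p anchor is
    known, the hairpin is flagged excluded if the learned end is offset from
    it by more than ``max_mature_offset`` nt.
    """
    if not control_calls:
        raise ValueError("reference_end_position requires at least one control call")
    ids = {c.hairpin_id for c in control_calls}
    if len(ids) != 1:
        raise ValueError(f"calls span multiple hairpins: {sorted(ids)}")
    counts = Counter(c.templated_end for c in control_calls)
    best_count = max(counts.values())
    reference_end = max(pos for pos, n in counts.items() if n == best_count)
    offset = None
    excluded = False
    if mature_3p_end is not None:
        offset = reference_end - mature_3p_end
        excluded = abs(offset) > max_mature_offset
    return EndAnnotation(
        hairpin_id=next(iter(ids)),
        reference_end=reference_end,
        excluded=excluded,
        offset_from_mature=offset,
    )


def _is_pure(tail: str, base: str) -> bool:
    return len(tail) > 0 and set(tail) == {base}


def classify(trim_len: int, tail_seq: str) -> str:
    """Read class as a function of (trim length, tail sequence) only."""
    if trim_len > 0:
        return CLASS_TRIMMED
    if trim_len == 0 and tail_seq == "":
        return CLASS_INTACT
    if trim_len == 0 and tail_seq == "U":
        return CLASS_MONO_U
    return CLASS_OTHER


def annotate_read(call: TailCall, end: EndAnnotation) -> AnnotatedRead:
    """Convert a tail call into trimming length, U-tail length and class."""
    if end.excluded:
        raise ValueError(f"{end.hairpin_id}: excluded hairpin cannot be annotated")
    if call.hairpin_id != end.hairpin_id:
        raise ValueError("call and end annotation refer to different hairpins")
    trim_len = end.reference_end - call.templated_end
    utail_len = len(call.nta) if _is_pure(call.nta, "U") else 0
    return AnnotatedRead(
        read_id=call.read_id,
        hairpin_id=call.hairpin_id,
        trim_len=trim_len,
        utail_len=utail_len,
        tail_seq=call.nta,
        read_class=classify(trim_len, call.nta),
    )


def learn_reference_ends(
    control_calls: Iterable[TailCall],
    mature_ends: dict[str, int] | None = None,
    max_mature_offset: int = 3,
    report: list[str] | None = None,
) -> dict[str, EndAnnotation]:
    """Reference ends for every hairpin seen in the control sample."""
    mature_ends = mature_ends or {}
    by_hairpin: dict[str, list[TailCall]] = {}
    for c in control_calls:
        by_hairpin.setdefault(c.hairpin_id, []).append(c)
    out = {}
    for hid, calls in by_hairpin.items():
        ann = reference_end_position(calls, mature_ends.get(hid), max_mature_offset)
        if ann.excluded and report is not None:
            report.append(
                f"{hid}: reference end {ann.reference_end} offset "
                f"{ann.offset_from_mature} nt from mature 3p end; excluded"
            )
        out[hid] = ann
    return out


def annotate_sample(
    calls: Iterable[TailCall],
    ends: dict[str, EndAnnotation],
    report: list[str] | None = None,
) -> list[AnnotatedRead]:
    """Annotate every call whose hairpin has a usable reference end."""
    out = []
    missing: set[str] = set()
    for c in calls:
        end = ends.get(c.hairpin_id)
        if end is None or end.excluded:
            missing.add(c.hairpin_id)
            continue
        out.append(annotate_read(c, end))
    if report is not None:
        for hid in sorted(missing):
            report.append(f"{hid}: no usable reference end; reads dropped")
    return out
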