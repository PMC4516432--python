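"""End-to-end drivers for the sequencing arm.

Targeted libraries contain massive read duplication (a handful of hairpins,
discrete trim/tail states), so alignment is performed once per unique
insert and the call is broadcast to all reads sharing it.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import pandas as pd

from . import cohort_stats, end_profile, tail_align
from .read_preprocess import ProcessedRead
from .refprep import HairpinReference
from .tail_align import AlignScoring, DEFAULT_SCORING, TailCall


def call_processed_reads(
    reads: Iterable[ProcessedRead],
    references: Sequence[HairpinReference],
    scoring: AlignScoring = DEFAULT_SCORING,
    min_identity: float = 0.70,
    rescue: bool = True,
) -> list[TailCall]:
    """Tail calls for every kept read; inserts are deduplicated internally."""
    kept = [r for r in reads if r.kept]
    cache: dict[str, TailCall | None] = {}
    out: list[TailCall] = []
    for r in kept:
        if r.insert not in cache:
            cache[r.insert] = tail_align.call_read(
                r.insert, references, scoring, min_identity, rescue=rescue
            )
        call = cache[r.insert]
        if call is not None:
            out.append(replace(call, read_id=r.read_id))
    return out


def profile_sample(
    calls: Iterable[TailCall],
    ends: dict[str, end_profile.EndAnnotation],
    sample_id: str = "",
    tail_mode: str = cohort_stats.TAIL_MODE_PURE,
) -> dict[str, cohort_stats.PremiRNAProfile]:
    """Annotate calls against learned reference ends and build profiles."""
    annotated = end_profile.annotate_sample(calls, ends)
    return cohort_stats.build_profiles(annotated, sample_id=sample_id, tail_mode=tail_mode)


def run_two_sample_analysis(
    control_calls: Sequence[TailCall],
    treatment_calls: Sequence[TailCall],
    references: Sequence[HairpinReference],
    min_reads: int = 400,
    tail_mode: str = cohort_stats.TAIL_MODE_PURE,
) -> dict[str, pd.DataFrame]:
    """Control-anchored two-sample workflow.

    Reference 3' ends are always learned from the control sample and
    applied to both samples; hairpins offset from the mature 3p anchor are
    excluded everywhere.
    """
    mature = {
        r.hairpin_id: r.mature_3p_end
        for r in references
        if r.mature_3p_end is not None
    }
    report: list[str] = []
    ends = end_profile.learn_reference_ends(control_calls, mature, report=report)
    out = {}
    for name, calls in (("control", control_calls), ("treatment", treatment_calls)):
        profiles = profile_sample(calls, ends, sample_id=name, tail_mode=tail_mode)
        out[name] = cohort_stats.cohort_summary(list(profiles.values()), min_reads=min_reads)
        out[f"{name}_species"] = cohort_stats.profiles_table(profiles)
    out["report"] = pd.DataFrame({"message": report})
    return out


def calls_table(calls: Iterable[TailCall]) -> pd.DataFrame:
    """TSV-ready per-read call table with alignment statistics."""
    rows = []
    for c in calls:
        aln = c.alignment
        rows.append(
            {
                "read_id": c.read_id,
                "hairpin_id": c.hairpin_id,
                "templated_end": c.templated_end,
                "templated_read_end": c.templated_read_end,
                "nta": c.nta,
                "rescued": c.rescued,
                "matched": aln.matched if aln else None,
                "mismatched": aln.mismatched if aln else None,
                "score": aln.score if aln else None,
            }
        )
    return pd.DataFrame(rows)
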