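"""Per-hairpin and cohort-level tailing statistics.

Aggregates annotated reads into per-hairpin profiles (tail ratios, class
fractions, a (trim length x U-tail length) count matrix for dot plots),
cohort summaries over hairpins with sufficient depth (> 400 reads,
strict), pooled group mono-uridylation percentages, and knockdown fold
changes of per-species proportions.

"Uridylated" means a non-empty pure-U tail, mirroring the U-tail length
definition; an alternative counting of any tail containing U is available
via ``tail_mode="any_u"``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .end_profile import CLASS_MONO_U, CLASS_TRIMMED, READ_CLASSES, AnnotatedRead

TAIL_MODE_PURE = "pure"
TAIL_MODE_ANY_U = "any_u"


def _is_uridylated(tail: str, mode: str) -> bool:
    if mode == TAIL_MODE_PURE:
        return len(tail) > 0 and set(tail) == {"U"}
    if mode == TAIL_MODE_ANY_U:
        return "U" in tail
    raise ValueError(f"unknown tail mode: {mode!r}")


@dataclass
class PremiRNAProfile:
    """Tailing profile of one hairpin in one sample."""

    hairpin_id: str
    sample_id: str
    total_reads: int
    counts: Counter = field(default_factory=Counter)  # (trim_len, utail_len) -> n
    class_fractions: dict[str, float] = field(default_factory=dict)
    uridylation_ratio: float = 0.0
    adenylation_ratio: float = 0.0
    trimmed_ratio: float = 0.0
    uridylation_of_trimmed: float = float("nan")


def build_profile(
    annotated: Sequence[AnnotatedRead],
    sample_id: str = "",
    tail_mode: str = TAIL_MODE_PURE,
) -> PremiRNAProfile:
    """Profile one hairpin in one sample from its annotated reads."""
    if not annotated:
        raise ValueError("build_profile requires at least one annotated read")
    ids = {r.hairpin_id for r in annotated}
    if len(ids) != 1:
        raise ValueError(f"reads span multiple hairpins: {sorted(ids)}")
    n = len(annotated)
    counts = Counter((r.trim_len, r.utail_len) for r in annotated)
    class_counts = Counter(r.read_class for r in annotated)
    n_u = sum(1 for r in annotated if _is_uridylated(r.tail_seq, tail_mode))
    n_a = sum(1 for r in annotated if len(r.tail_seq) > 0 and set(r.tail_seq) == {"A"})
    trimmed = [r for r in annotated if r.trim_len > 0]
    n_trim_u = sum(1 for r in trimmed if _is_uridylated(r.tail_seq, tail_mode))
    return PremiRNAProfile(
        hairpin_id=next(iter(ids)),
        sample_id=sample_id,
        total_reads=n,
        counts=counts,
        class_fractions={c: class_counts.get(c, 0) / n for c in READ_CLASSES},
        uridylation_ratio=n_u / n,
        adenylation_ratio=n_a / n,
        trimmed_ratio=len(trimmed) / n,
        uridylation_of_trimmed=(n_trim_u / len(trimmed)) if trimmed else float("nan"),
    )


def build_profiles(
    annotated: Iterable[AnnotatedRead],
    sample_id: str = "",
    tail_mode: str = TAIL_MODE_PURE,
) -> dict[str, PremiRNAProfile]:
    by_hairpin: dict[str, list[AnnotatedRead]] = {}
    for r in annotated:
        by_hairpin.setdefault(r.hairpin_id, []).append(r)
    return {
        hid: build_profile(reads, sample_id=sample_id, tail_mode=tail_mode)
        for hid, reads in by_hairpin.items()
    }


def cohort_summary(
    profiles: Sequence[PremiRNAProfile],
    min_reads: int = 400,
) -> pd.DataFrame:
    """Per-hairpin table over hairpins with total_reads strictly > min_reads.

    The returned frame carries cohort medians of trimmed_ratio,
    uridylation_ratio and uridylation_of_trimmed in ``DataFrame.attrs``.
    Empty after filtering -> empty frame with a warning in attrs.
    """
    kept = [p for p in profiles if p.total_reads > min_reads]
    rows = [
        {
            "hairpin_id": p.hairpin_id,
            "sample_id": p.sample_id,
            "total_reads": p.total_reads,
            "trimmed_ratio": p.trimmed_ratio,
            "uridylation_ratio": p.uridylation_ratio,
            "adenylation_ratio": p.adenylation_ratio,
            "uridylation_of_trimmed": p.uridylation_of_trimmed,
            **{f"frac_{c}": p.class_fractions.get(c, 0.0) for c in READ_CLASSES},
        }
        for p in sorted(kept, key=lambda p: p.hairpin_id)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "hairpin_id",
            "sample_id",
            "total_reads",
            "trimmed_ratio",
            "uridylation_ratio",
            "adenylation_ratio",
            "uridylation_of_trimmed",
            *[f"frac_{c}" for c in READ_CLASSES],
        ],
    )
    if df.empty:
        df.attrs["warning"] = f"no hairpin exceeds {min_reads} reads"
        df.attrs["medians"] = {}
    else:
        df.attrs["medians"] = {
            col: float(df[col].median())
            for col in ("trimmed_ratio", "uridylation_ratio", "uridylation_of_trimmed")
        }
    return df


def group_mono_u_percent(
    annotated: Iterable[AnnotatedRead],
    group_members: Sequence[str],
) -> float:
    """Mono-uridylation percentage of a hairpin group, pooling reads across
    the group's hairpins and normalizing by the pooled total read count."""
    members = set(group_members)
    total = mono_u = 0
    for r in annotated:
        if r.hairpin_id not in members:
            continue
        total += 1
        if r.read_class == CLASS_MONO_U:
            mono_u += 1
    if total == 0:
        raise ValueError("no reads for the requested group")
    return 100.0 * mono_u / total


def class_percentages(annotated: Iterable[AnnotatedRead]) -> dict[str, float]:
    """Intact/Mono-U/Trimmed/Other percentages of a pooled read set."""
    counts = Counter(r.read_class for r in annotated)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads")
    return {c: 100.0 * counts.get(c, 0) / total for c in READ_CLASSES}


def condition_fold_change(p_ctrl: float, p_kd: float) -> float:
    """Knockdown / control proportion ratio; NaN when the control is zero."""
    if p_ctrl < 0 or p_kd < 0:
        raise ValueError("proportions must be non-negative")
    if p_ctrl == 0:
        return float("nan")
    return p_kd / p_ctrl


def species_proportions(profile: PremiRNAProfile) -> dict[tuple[int, int], float]:
    """Per-(trim, U-tail) species proportions (%) within one hairpin."""
    return {
        key: 100.0 * n / profile.total_reads for key, n in sorted(profile.counts.items())
    }


def dotplot_matrix(
    profile: PremiRNAProfile,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative-abundance matrix over (trim length, U-tail length).

    Returns ``(matrix, trim_lengths, utail_lengths)``; rows follow
    ``trim_lengths`` (nt, 0 at the reference end; negative = extended) and
    columns follow ``utail_lengths``.  Entries sum to 1.
    """
    if profile.total_reads <= 0:
        raise ValueError("dotplot requires total_reads > 0")
    trims = np.array(sorted({t for t, _ in profile.counts}))
    tails = np.array(sorted({u for _, u in profile.counts}))
    mat = np.zeros((len(trims), len(tails)))
    trim_idx = {t: i for i, t in enumerate(trims)}
    tail_idx = {u: j for j, u in enumerate(tails)}
    for (t, u), n in profile.counts.items():
        mat[trim_idx[t], tail_idx[u]] = n
    return mat / profile.total_reads, trims, tails


def plot_dotplot(profile: PremiRNAProfile, ax=None, max_area: float = 400.0):
    """Draw the trimming-by-U-tail dot plot (circle area ~ abundance)."""
    import matplotlib.pyplot as plt

    mat, trims, tails = dotplot_matrix(profile)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    xs, ys, areas = [], [], []
    for i, t in enumerate(trims):
        for j, u in enumerate(tails):
            if mat[i, j] > 0:
                xs.append(t)
                ys.append(u)
                areas.append(max_area * mat[i, j])
    ax.scatter(xs, ys, s=areas, alpha=0.7, edgecolors="k", linewidths=0.5)
    ax.set_xlabel("length of 3' trimming (nt)")
    ax.set_ylabel("length of U-tail (nt)")
    ax.set_title(f"{profile.hairpin_id} ({profile.sample_id})")
    ax.invert_xaxis()
    return ax


def profiles_table(profiles: Mapping[str, PremiRNAProfile]) -> pd.DataFrame:
    """Tidy per-(hairpin, trim, utail) count table for export."""
    rows = []
    for p in profiles.values():
        for (t, u), n in sorted(p.counts.items()):
            rows.append(
                {
                    "hairpin_id": p.hairpin_id,
                    "sample_id": p.sample_id,
                    "trim_len": t,
                    "utail_len": u,
                    "count": n,
                    "fraction": n / p.total_reads,
                }
            )
    return pd.DataFrame(rows)


def binomial_ci(p_hat: float, n: int, confidence: float = 0.99) -> tuple[float, float]:
    """Normal-approximation binomial interval, clipped to [0, 1]."""
    from scipy import stats

    z = stats.norm.ppf(0.5 + confidence / 2)
    half = z * math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n)
    return max(0.0, p_hat - half), min(1.0, p_hat + half)
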