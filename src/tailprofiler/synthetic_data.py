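"""Ground-truth generators for all three experimental arms.

Every generator is seed-deterministic (same seed, byte-identical output)
and returns the generating truth alongside the data, so each pipeline
stage can be tested as recovery of a known quantity.

* :func:`simulate_library` emits targeted pre-miRNA reads: a fixed-length
  primer prefix (the enrichment primer, covering the hairpin 5' end), the
  hairpin sequence recessed 3' by a drawn trimming length, a drawn
  non-templated tail, the 3' adapter, and a constant fill to the read
  length, with substitution errors in the hairpin-derived portion.
* :func:`simulate_traces` emits single-molecule intensity time series as
  an alternating renewal process: exponential waits between binding
  events (rate k_on), exponential dwells (rate k_off), Gaussian noise.
* :func:`simulate_lane` emits gel lane profiles as Gaussian bands on a
  baseline, with a marker lane generated through the same position-size
  model (affine by default: migration distance decreases linearly with
  RNA size).

:func:`make_test_references` builds synthetic hairpins whose 3'-terminal
region is G/C-only, so that any added A/U tail mismatches the template
immediately.  Real pre-miRNAs frequently end in genomic A/U runs, which
makes a terminal U indistinguishable from template (tail rates are then
systematically conservative); the G/C 3' design removes that ambiguity so
recovery tests compare against an exactly identifiable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .end_profile import classify
from .gel_quant import LaneProfile
from .refprep import HairpinRecord, HairpinReference, build_reference_set
from .sm_kinetics import Trace
from .tail_align import to_rna

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTC"
_BASES = np.array(list("ACGT"))


def _geometric_pmf(support: np.ndarray, p: float) -> np.ndarray:
    w = (1 - p) ** (support - support.min())
    return w / w.sum()


# ---------------------------------------------------------------------------
# Sequencing arm


@dataclass(frozen=True)
class LibraryTruth:
    """Generating distributions for one synthetic targeted library.

    Category probabilities are per read: ``mono_u_fraction`` reads carry
    (trim 0, tail U); ``trimmed_fraction`` reads draw a positive trimming
    length from ``trim_len_dist`` and a tail model from
    ``p_tail_given_trimmed``; of the remaining untrimmed reads,
    ``untrimmed_pure_a_fraction`` carry a pure-A tail and the rest are
    intact.
    """

    n_reads: int = 10_000
    mono_u_fraction: float = 0.362
    trimmed_fraction: float = 0.3
    untrimmed_pure_a_fraction: float = 0.02
    trim_len_dist: dict[int, float] = field(
        default_factory=lambda: {
            k: float(w)
            for k, w in zip(
                range(1, 13), _geometric_pmf(np.arange(1, 13), 0.2)
            )
        }
    )
    p_tail_given_trimmed: dict[str, float] = field(
        default_factory=lambda: {"U": 0.30, "A": 0.05, "mixed": 0.05, "none": 0.60}
    )
    tail_len_dist: dict[int, float] = field(
        default_factory=lambda: {
            k: float(w)
            for k, w in zip(range(1, 9), _geometric_pmf(np.arange(1, 9), 0.35))
        }
    )
    subst_error_rate: float = 0.001
    read_length: int = 110

    def __post_init__(self) -> None:
        if not (
            0 <= self.mono_u_fraction
            and 0 <= self.trimmed_fraction
            and self.mono_u_fraction + self.trimmed_fraction <= 1
        ):
            raise ValueError("category probabilities must be in [0,1] and sum <= 1")


def make_test_references(
    n_hairpins: int = 3,
    core_len: int = 72,
    extension_nt: int = 10,
    gc_tail_len: int = 20,
    seed: int = 0,
) -> list[HairpinReference]:
    """Synthetic hairpin references with a G/C-only 3'-terminal region.

    The last ``gc_tail_len`` core bases and the whole 3' flank are drawn
    from {G, C} so that non-templated A/U tails always mismatch the
    template at their first base (see module docstring).  The mature-3p
    end is placed at the last core base.
    """
    rng = np.random.default_rng(seed)
    records = []
    mature = {}
    for i in range(n_hairpins):
        hid = f"syn-mir-{i + 1}"
        head = rng.choice(_BASES, size=extension_nt + core_len - gc_tail_len)
        tail = rng.choice(np.array(list("GC")), size=gc_tail_len + extension_nt)
        contig = "".join(head) + "".join(tail)
        records.append(HairpinRecord(hid, contig, extension_nt, extension_nt + core_len))
        mature[hid] = core_len - 1
    return build_reference_set(records, mature, extension_nt=extension_nt)


def _draw_from(dist: dict, rng: np.random.Generator):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _draw_tail(kind: str, truth: LibraryTruth, rng: np.random.Generator) -> str:
    """Tail in DNA alphabet."""
    if kind == "none":
        return ""
    length = _draw_from(truth.tail_len_dist, rng)
    if kind == "U":
        return "T" * length
    if kind == "A":
        return "A" * length
    # mixed: at least two distinct bases among A/T/G/C, U-biased
    while True:
        tail = "".join(rng.choice(_BASES, size=max(2, length), p=[0.3, 0.1, 0.1, 0.5]))
        if len(set(tail)) > 1:
            return tail


def simulate_library(
    refs: list[HairpinReference],
    truth: LibraryTruth = LibraryTruth(),
    adapter: str = DEFAULT_ADAPTER,
    primer_len: int = 15,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate raw reads plus a per-read truth table.

    Returns ``(reads, truth_table)`` where reads are (read_id, sequence)
    pairs of length ``truth.read_length`` and the table records hairpin,
    trimming length, tail (RNA alphabet), read class and error count.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    rows = []
    hp_index = rng.integers(0, len(refs), size=truth.n_reads)
    for i in range(truth.n_reads):
        ref = refs[hp_index[i]]
        u = rng.random()
        if u < truth.mono_u_fraction:
            trim, tail = 0, "T"
        elif u < truth.mono_u_fraction + truth.trimmed_fraction:
            trim = _draw_from(truth.trim_len_dist, rng)
            tail = _draw_tail(_draw_from(truth.p_tail_given_trimmed, rng), truth, rng)
        elif rng.random() < truth.untrimmed_pure_a_fraction:
            trim, tail = 0, "A" * _draw_from(truth.tail_len_dist, rng)
        else:
            trim, tail = 0, ""
        end = ref.canonical_end  # 0-based last templated base when trim = 0
        body = ref.sequence[ref.core_start : end + 1 - trim]
        primer = body[:primer_len]
        insert = list(body[primer_len:])
        n_err = 0
        for j in range(len(insert)):
            if rng.random() < truth.subst_error_rate:
                insert[j] = rng.choice(_BASES[_BASES != insert[j]])
                n_err += 1
        raw = primer + "".join(insert) + tail + adapter
        raw = (raw + "G" * truth.read_length)[: truth.read_length]
        read_id = f"read{i:06d}"
        reads.append((read_id, raw))
        rows.append(
            {
                "read_id": read_id,
                "hairpin_id": ref.hairpin_id,
                "trim_len": trim,
                "tail_seq": to_rna(tail),
                "read_class": classify(trim, to_rna(tail)),
                "n_errors": n_err,
            }
        )
    return reads, pd.DataFrame(rows)


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Single-molecule arm


@dataclass(frozen=True)
class TraceTruth:
    """Generating parameters for synthetic binding traces."""

    k_on: float = 0.2  # arrivals per second while unbound
    k_off: float = 2.78  # dissociations per second while bound
    duration: float = 300.0  # seconds
    time_step: float = 0.1  # seconds (0.03-0.1 s camera resolution)
    baseline: float = 100.0
    amplitude: float = 500.0
    noise_sd: float = 30.0
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.duration, self.time_step) <= 0:
            raise ValueError("rates, duration and time_step must be positive")


def draw_dwells(n: int, k_off: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. exponential dwell times (seconds) with rate ``k_off``."""
    return rng.exponential(1.0 / k_off, size=n)


def simulate_traces(
    truth: TraceTruth,
    n_molecules: int,
    seed: int = 0,
) -> tuple[list[Trace], pd.DataFrame]:
    """Alternating-renewal binding traces plus a per-event truth table."""
    rng = np.random.default_rng(seed)
    n_frames = int(round(truth.duration / truth.time_step))
    traces = []
    rows = []
    for m in range(n_molecules):
        occupancy = np.zeros(n_frames)
        t = 0.0
        while True:
            t += rng.exponential(1.0 / truth.k_on)
            if t >= truth.duration:
                break
            dwell = rng.exponential(1.0 / truth.k_off)
            start = t
            end = min(t + dwell, truth.duration)
            s_frame = int(start / truth.time_step)
            e_frame = min(n_frames, int(np.ceil(end / truth.time_step)))
            occupancy[s_frame:e_frame] = 1.0
            rows.append(
                {
                    "molecule_id": f"mol{m:04d}",
                    "start_s": start,
                    "dwell_s": dwell,
                    "censored": t + dwell > truth.duration,
                }
            )
            t += dwell
        intensity = (
            truth.baseline
            + truth.amplitude * occupancy
            + rng.normal(0.0, truth.noise_sd, size=n_frames)
            if truth.noise_sd > 0
            else truth.baseline + truth.amplitude * occupancy
        )
        traces.append(
            Trace(time_step=truth.time_step, channels=(intensity,), molecule_id=f"mol{m:04d}")
        )
    return traces, pd.DataFrame(
        rows, columns=["molecule_id", "start_s", "dwell_s", "censored"]
    )


# ---------------------------------------------------------------------------
# Gel arm


@dataclass(frozen=True)
class GelTruth:
    """Generating parameters for synthetic gel lanes.

    Migration position is affine in RNA size by default: position =
    ``origin_px - px_per_nt * size`` (smaller RNA migrates further, i.e.
    to larger positions), optionally logarithmic: position = origin_px -
    log_scale_px * ln(size).
    """

    band_sizes: tuple[float, ...] = (76.0,)
    band_fractions: tuple[float, ...] = (1.0,)
    band_sigma_px: float = 4.0
    # phosphorimager-like counts: peak height ~2.5e4 for a sigma-4 band, the
    # regime in which the default marker-curvature threshold is meaningful
    total_mass: float = 2.5e5
    marker_sizes: tuple[float, ...] = (60.0, 70.0, 80.0, 90.0, 100.0)
    baseline: float = 50.0
    noise_sd: float = 0.0
    origin_px: float = 1400.0
    px_per_nt: float = 12.0
    log_model: bool = False
    log_scale_px: float = 900.0

    def __post_init__(self) -> None:
        if len(self.band_sizes) != len(self.band_fractions):
            raise ValueError("band_sizes and band_fractions length mismatch")
        if abs(sum(self.band_fractions) - 1.0) > 1e-9:
            raise ValueError("band mass fractions must sum to 1")

    def position_of(self, size) -> np.ndarray:
        size = np.asarray(size, dtype=float)
        if self.log_model:
            return self.origin_px - self.log_scale_px * np.log(size)
        return self.origin_px - self.px_per_nt * size


def _bands(
    positions: np.ndarray,
    centers: np.ndarray,
    masses: np.ndarray,
    sigma: float,
) -> np.ndarray:
    out = np.zeros_like(positions)
    for c, m in zip(centers, masses):
        out += m * np.exp(-0.5 * ((positions - c) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
    return out


def simulate_lane(
    truth: GelTruth,
    length_px: int = 2000,
    seed: int = 0,
) -> tuple[LaneProfile, LaneProfile, pd.DataFrame]:
    """One sample lane plus a marker lane through the same size model.

    Returns ``(lane, marker_lane, truth_table)`` where the table lists each
    band's size, mass fraction and true center position (and the marker
    band positions for the marker lane).
    """
    rng = np.random.default_rng(seed)
    px = np.arange(length_px, dtype=float)
    centers = truth.position_of(np.array(truth.band_sizes))
    if np.any(centers < 0) or np.any(centers >= length_px):
        raise ValueError("band positions fall outside the lane")
    masses = truth.total_mass * np.asarray(truth.band_fractions)
    lane = truth.baseline + _bands(px, centers, masses, truth.band_sigma_px)
    marker_centers = truth.position_of(np.array(truth.marker_sizes))
    if np.any(marker_centers < 0) or np.any(marker_centers >= length_px):
        raise ValueError("marker positions fall outside the lane")
    marker = truth.baseline + _bands(
        px,
        marker_centers,
        np.full(len(marker_centers), truth.total_mass),
        truth.band_sigma_px,
    )
    if truth.noise_sd > 0:
        lane = np.clip(lane + rng.normal(0, truth.noise_sd, length_px), 0, None)
        marker = np.clip(marker + rng.normal(0, truth.noise_sd, length_px), 0, None)
    rows = [
        {"lane": "sample", "size_nt": s, "mass_fraction": f, "center_px": c}
        for s, f, c in zip(truth.band_sizes, truth.band_fractions, centers)
    ] + [
        {"lane": "marker", "size_nt": s, "mass_fraction": None, "center_px": c}
        for s, c in zip(truth.marker_sizes, marker_centers)
    ]
    return LaneProfile(lane), LaneProfile(marker), pd.DataFrame(rows)
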