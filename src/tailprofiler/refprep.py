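"""Extended hairpin reference construction.

Reads sequenced from targeted pre-miRNA libraries frequently run past the
annotated hairpin boundaries (untrimmed Drosha products, templated
extensions).  To avoid misalignment artifacts near the annotated ends, each
hairpin span is extended by a fixed number of genomic flank nucleotides on
both sides (default 10), clamped at contig boundaries.  All downstream
coordinates (templated 3' ends, trimming lengths) are expressed on this
extended sequence.

Coordinates are 0-based, half-open throughout; 3'-end positions are 0-based
indices of a *last* base.  Uracil in any input is canonicalized to T; the
stored alphabet is DNA (A/C/G/T/N).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = set("ACGTN")


def canonicalize(seq: str) -> str:
    """Uppercase and convert U to T. Raises on symbols outside A/C/G/T/N/U."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class HairpinRecord:
    """One hairpin span on a contig, before extension."""

    hairpin_id: str
    contig_seq: str
    start: int  # 0-based, half-open span on the contig
    end: int


@dataclass(frozen=True)
class HairpinReference:
    """An extended hairpin reference sequence.

    ``sequence`` is the hairpin plus up to ``extension_nt`` genomic flank
    bases on each side; ``core_start:core_end`` slices out the unextended
    hairpin.  ``mature_3p_end`` is the 0-based index (in extended
    coordinates) of the last base of the mature miRNA from the 3' arm, when
    annotated.
    """

    hairpin_id: str
    sequence: str
    core_start: int
    core_end: int
    extension_nt: int = 10
    mature_3p_end: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.core_start <= self.extension_nt):
            raise ValueError(
                f"{self.hairpin_id}: core_start {self.core_start} outside "
                f"[0, extension_nt={self.extension_nt}]"
            )
        right = len(self.sequence) - self.core_end
        if not (0 <= right <= self.extension_nt):
            raise ValueError(
                f"{self.hairpin_id}: right flank {right} outside "
                f"[0, extension_nt={self.extension_nt}]"
            )
        if set(self.sequence) - _DNA:
            raise ValueError(f"{self.hairpin_id}: sequence not canonical DNA")

    @property
    def core_sequence(self) -> str:
        return self.sequence[self.core_start : self.core_end]

    @property
    def canonical_end(self) -> int:
        """Default 3'-end anchor: the annotated mature 3p end when present,
        otherwise the last base of the unextended hairpin."""
        if self.mature_3p_end is not None:
            return self.mature_3p_end
        return self.core_end - 1


def build_reference_set(
    hairpin_records: Iterable[HairpinRecord],
    mature_records: Mapping[str, int] | None = None,
    extension_nt: int = 10,
    report: list[str] | None = None,
) -> list[HairpinReference]:
    """Extend each hairpin span by ``extension_nt`` flank bases per side.

    Parameters
    ----------
    hairpin_records
        Hairpin spans with their contig sequences.
    mature_records
        Optional map hairpin_id -> 0-based index of the last mature-3p base
        *in unextended hairpin coordinates*; remapped into extended
        coordinates on output.
    extension_nt
        Flank length per side; clamped where the contig ends.
    report
        Optional list collecting human-readable skip reasons for rejected
        records.

    Raises
    ------
    ValueError
        On a duplicate hairpin_id.
    """
    if extension_nt < 0:
        raise ValueError("extension_nt must be >= 0")
    mature_records = mature_records or {}
    out: list[HairpinReference] = []
    seen: set[str] = set()
    for rec in hairpin_records:
        if rec.hairpin_id in seen:
            raise ValueError(f"duplicate hairpin_id: {rec.hairpin_id}")
        seen.add(rec.hairpin_id)
        contig = canonicalize(rec.contig_seq)
        if not (0 <= rec.start < rec.end <= len(contig)):
            if report is not None:
                report.append(
                    f"{rec.hairpin_id}: span [{rec.start}, {rec.end}) outside "
                    f"contig of length {len(contig)}; skipped"
                )
            continue
        ext_start = max(0, rec.start - extension_nt)
        ext_end = min(len(contig), rec.end + extension_nt)
        core_start = rec.start - ext_start
        core_end = core_start + (rec.end - rec.start)
        mature = mature_records.get(rec.hairpin_id)
        mature_ext = core_start + mature if mature is not None else None
        out.append(
            HairpinReference(
                hairpin_id=rec.hairpin_id,
                sequence=contig[ext_start:ext_end],
                core_start=core_start,
                core_end=core_end,
                extension_nt=extension_nt,
                mature_3p_end=mature_ext,
            )
        )
    return out


# ---------------------------------------------------------------------------
# File interfaces


def load_hairpin_records(genome_fasta: str | Path, bed_path: str | Path) -> list[HairpinRecord]:
    """Read hairpin spans from a BED file (0-based half-open) against a
    genome FASTA.  Only columns chrom/start/end/name are used; the library is
    strand-specific (hairpin sense), so the strand column is ignored."""
    contigs = {r.id: str(r.seq) for r in SeqIO.parse(str(genome_fasta), "fasta")}
    records = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            if chrom not in contigs:
                raise ValueError(f"BED contig {chrom!r} not in genome FASTA")
            records.append(HairpinRecord(name, contigs[chrom], start, end))
    return records


def load_mature_annotations(tsv_path: str | Path) -> dict[str, int]:
    """TSV with columns hairpin_id, mature_3p_end (0-based, core coords)."""
    out: dict[str, int] = {}
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["hairpin_id"]] = int(row["mature_3p_end"])
    return out


def write_reference_set(
    refs: Sequence[HairpinReference], fasta_path: str | Path, index_path: str | Path
) -> None:
    """Write extended FASTA plus a TSV index (id, core span, mature end)."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.hairpin_id, description="") for r in refs),
        str(fasta_path),
        "fasta",
    )
    with open(index_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["hairpin_id", "core_start", "core_end", "extension_nt", "mature_3p_end"])
        for r in refs:
            w.writerow(
                [
                    r.hairpin_id,
                    r.core_start,
                    r.core_end,
                    r.extension_nt,
                    "" if r.mature_3p_end is None else r.mature_3p_end,
                ]
            )


def read_reference_set(fasta_path: str | Path, index_path: str | Path) -> list[HairpinReference]:
    """Inverse of :func:`write_reference_set`."""
    seqs = {r.id: canonicalize(str(r.seq)) for r in SeqIO.parse(str(fasta_path), "fasta")}
    refs = []
    with open(index_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            refs.append(
                HairpinReference(
                    hairpin_id=row["hairpin_id"],
                    sequence=seqs[row["hairpin_id"]],
                    core_start=int(row["core_start"]),
                    core_end=int(row["core_end"]),
                    extension_nt=int(row["extension_nt"]),
                    mature_3p_end=int(row["mature_3p_end"]) if row["mature_3p_end"] else None,
                )
            )
    return refs
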