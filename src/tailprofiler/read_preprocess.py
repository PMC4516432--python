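"""Raw-read preprocessing: 5' primer trimming and 3' adapter clipping.

Targeted pre-miRNA libraries carry 15 primer-derived bases at the read 5'
end (enrichment PCR primers, frequently mismatched to the hairpin) and a
ligated 3' adapter.  A read becomes an alignable insert by removing the
fixed-length primer prefix and everything from the leftmost adapter
occurrence onward.  Reads without a recognizable adapter, or whose insert is
shorter than 15 nt, are dropped.

Adapter matching is a leftmost approximate match: at each candidate start
position the overlapping adapter prefix (possibly truncated at the read 3'
end, minimum overlap 5 nt) is compared by Hamming distance, accepting up to
``floor(rate * overlap)`` mismatches.  Quality strings are carried through
unmodified but never used for filtering.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

from .refprep import canonicalize

DROP_NONE = "none"
DROP_NO_ADAPTER = "no_adapter"
DROP_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    insert: str
    drop_reason: str = DROP_NONE
    quality: str | None = None
    adapter_start: int | None = None  # position in the trimmed read

    @property
    def kept(self) -> bool:
        return self.drop_reason == DROP_NONE


def find_adapter(
    seq: str,
    adapter: str,
    max_mismatch_rate: float = 0.1,
    min_overlap: int = 5,
) -> int | None:
    """Leftmost start of an approximate adapter occurrence in ``seq``.

    The adapter may be truncated at the 3' end of ``seq`` down to
    ``min_overlap`` bases.  Returns None when no position qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(seq), len(adapter)
    for start in range(0, n - min_overlap + 1):
        overlap = min(m, n - start)
        allowed = int(max_mismatch_rate * overlap)
        mismatches = 0
        ok = True
        for i in range(overlap):
            if seq[start + i] != adapter[i]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return start
    return None


def preprocess_read(
    raw: str,
    adapter: str,
    five_prime_trim: int = 15,
    min_len: int = 15,
    max_adapter_mismatch_rate: float = 0.1,
    min_adapter_overlap: int = 5,
    read_id: str = "",
    quality: str | None = None,
) -> ProcessedRead:
    """Trim the primer prefix, clip the 3' adapter, and length-filter."""
    raw = canonicalize(raw)
    adapter = canonicalize(adapter)
    if len(raw) < five_prime_trim:
        return ProcessedRead(read_id, "", DROP_TOO_SHORT, quality)
    trimmed = raw[five_prime_trim:]
    qual_trimmed = quality[five_prime_trim:] if quality is not None else None
    hit = find_adapter(trimmed, adapter, max_adapter_mismatch_rate, min_adapter_overlap)
    if hit is None:
        return ProcessedRead(read_id, "", DROP_NO_ADAPTER, qual_trimmed)
    insert = trimmed[:hit]
    qual = qual_trimmed[:hit] if qual_trimmed is not None else None
    if len(insert) < min_len:
        return ProcessedRead(read_id, insert, DROP_TOO_SHORT, qual, hit)
    return ProcessedRead(read_id, insert, DROP_NONE, qual, hit)


# ---------------------------------------------------------------------------
# FASTQ interface


def _open_maybe_gzip(path: str | Path) -> TextIO:
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def preprocess_fastq(
    fastq_path: str | Path,
    adapter: str,
    five_prime_trim: int = 15,
    min_len: int = 15,
    max_adapter_mismatch_rate: float = 0.1,
) -> Iterator[ProcessedRead]:
    """Stream a FASTQ (optionally gzipped) through :func:`preprocess_read`."""
    with _open_maybe_gzip(fastq_path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield preprocess_read(
                str(rec.seq),
                adapter,
                five_prime_trim=five_prime_trim,
                min_len=min_len,
                max_adapter_mismatch_rate=max_adapter_mismatch_rate,
                read_id=rec.id,
                quality=qual,
            )


def write_inserts_fastq(reads: Iterable[ProcessedRead], out_path: str | Path) -> int:
    """Write kept inserts as FASTQ; returns the number written."""
    n = 0
    with open(out_path, "w") as fh:
        for r in reads:
            if not r.kept:
                continue
            qual = r.quality if r.quality is not None else "I" * len(r.insert)
            fh.write(f"@{r.read_id}\n{r.insert}\n+\n{qual}\n")
            n += 1
    return n


def write_drop_report(reads: Iterable[ProcessedRead], out_path: str | Path) -> None:
    with open(out_path, "w") as fh:
        fh.write("read_id\tdrop_reason\n")
        for r in reads:
            if not r.kept:
                fh.write(f"{r.read_id}\t{r.drop_reason}\n")
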