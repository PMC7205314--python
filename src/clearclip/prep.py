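"""Read preprocessing: quality filter, 3' adapter trim, 5' barcode strip,
identical-read collapapse and minimum-length filter.

The degenerate 3-nt barcode at the read 5' end acts as a UMI against
preferential PCR duplication, so the default duplicate key is the
(barcode, sequence) pair; ``collapse_on_sequence_only=True`` collapses on
sequence alone instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO

from .config import ADAPTER_3P, BARCODE_LEN

MIN_LEN_DEFAULT = 16
MEAN_PHRED_MIN = 20.0


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: List[int]
    barcode: str = ""
    dup_count: int = 1

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class PrepStats:
    n_input: int = 0
    n_low_quality: int = 0
    n_too_short_barcode: int = 0
    n_too_short: int = 0
    n_kept_unique: int = 0
    n_kept_reads: int = 0
    extra: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("extra")
        d.update(self.extra)
        return d


def read_fastq(path: str | Path) -> List[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(ReadRecord(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    return out


def mean_quality(read: ReadRecord) -> float:
    return sum(read.quality) / len(read.quality) if read.quality else 0.0


def trim_adapter(
    read: ReadRecord,
    adapter: str = ADAPTER_3P,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
) -> ReadRecord:
    """Remove the leftmost adapter occurrence and everything 3' of it.

    A full adapter anywhere in the read, or an adapter *prefix* of at least
    ``min_overlap`` nt at the read's 3' terminus, is trimmed when its mismatch
    rate is <= ``max_mismatch_rate``. Quality is trimmed in lockstep; reads
    with no adapter pass through unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    n, alen = len(seq), len(adapter)
    for start in range(0, n - min_overlap + 1):
        span = min(alen, n - start)
        if span < min_overlap and span < alen:
            break
        mism = sum(1 for a, b in zip(seq[start : start + span], adapter[:span]) if a != b)
        if mism <= max_mismatch_rate * span:
            return ReadRecord(
                read.read_id, seq[:start], read.quality[:start], read.barcode, read.dup_count
            )
    return read


def strip_barcode(read: ReadRecord, barcode_len: int = BARCODE_LEN) -> ReadRecord | None:
    """Move the first ``barcode_len`` bases into the barcode field.

    Returns None (read discarded) when the read is not longer than the
    barcode.
    """
    if len(read.sequence) <= barcode_len:
        return None
    return ReadRecord(
        read.read_id,
        read.sequence[barcode_len:],
        read.quality[barcode_len:],
        read.sequence[:barcode_len],
        read.dup_count,
    )


def collapse_and_filter(
    reads: Iterable[ReadRecord],
    min_len: int = MIN_LEN_DEFAULT,
    collapse_on_sequence_only: bool = False,
) -> Tuple[List[ReadRecord], PrepStats]:
    """Collapse identical reads and drop those shorter than ``min_len``.

    One output record per distinct key with ``dup_count`` = multiplicity
    (summing input dup_counts, so the operation is idempotent). The
    representative keeps the first-seen read id and quality.
    """
    stats = PrepStats()
    seen: Dict[Tuple[str, str], ReadRecord] = {}
    for r in reads:
        stats.n_input += 1
        if len(r.sequence) < min_len:
            stats.n_too_short += 1
            continue
        stats.n_kept_reads += r.dup_count
        key = ("", r.sequence) if collapse_on_sequence_only else (r.barcode, r.sequence)
        if key in seen:
            seen[key].dup_count += r.dup_count
        else:
            seen[key] = ReadRecord(r.read_id, r.sequence, r.quality, r.barcode, r.dup_count)
    kept = list(seen.values())
    stats.n_kept_unique = len(kept)
    return kept, stats


def prepare_reads(
    reads: Iterable[ReadRecord],
    adapter: str = ADAPTER_3P,
    barcode_len: int = BARCODE_LEN,
    min_len: int = MIN_LEN_DEFAULT,
    min_mean_quality: float = MEAN_PHRED_MIN,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    collapse_on_sequence_only: bool = False,
) -> Tuple[List[ReadRecord], PrepStats]:
    """Full preprocessing: quality filter -> adapter trim -> barcode strip ->
    collapse + length filter. Count conservation:
    n_input = n_low_quality + n_too_short_barcode + n_too_short + kept reads.
    """
    cleaned: List[ReadRecord] = []
    n_low_q = 0
    n_short_bc = 0
    for r in reads:
        if mean_quality(r) < min_mean_quality:
            n_low_q += 1
            continue
        r = trim_adapter(r, adapter, min_overlap, max_mismatch_rate)
        stripped = strip_barcode(r, barcode_len)
        if stripped is None:
            n_short_bc += 1
            continue
        cleaned.append(stripped)
    kept, stats = collapse_and_filter(cleaned, min_len, collapse_on_sequence_only)
    stats.n_input += n_low_q + n_short_bc
    stats.n_low_quality = n_low_q
    stats.n_too_short_barcode = n_short_bc
    return kept, stats


def write_collapsed_fasta(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    """Collapsed reads as FASTA with `readid|dup=N|bc=XYZ` headers."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}|dup={r.dup_count}|bc={r.barcode}\n{r.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> List[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        dup = 1
        bc = ""
        for p in parts[1:]:
            if p.startswith("dup="):
                dup = int(p[4:])
            elif p.startswith("bc="):
                bc = p[3:]
        seq = str(rec.seq)
        out.append(ReadRecord(parts[0], seq, [40] * len(seq), bc, dup))
    return out
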