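"""Read classification: chimera / miRNA-only / CLIP / ncRNA / unmapped.

A cleaned read is searched for a mature miRNA (local alignment, E < 0.4); the
residual sequence next to the miRNA is extracted and mapped to the
transcriptome. Reads whose target maps to rRNA/tRNA/miRNA loci are removed as
ncRNA; reads without a miRNA but with a transcript hit are CLIP single reads
carrying Ago binding sites; multi-best-hit target segments are flagged and
excluded from unique-interaction building.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .align import (
    DEFAULT_EVALUE_MAX,
    WORD_MIRNA,
    WORD_TRANSCRIPT,
    AlignmentHit,
    KmerIndex,
    best_hit,
)
from .prep import ReadRecord

MIN_TARGET_LEN = 16
MAX_LINKER_SLACK = 6  # residual < 6 nt on the minor side tolerated as linker slack

CLASSES = ("chimera", "mirna_only", "clip", "ncRNA", "unmapped", "ambiguous", "multimapped")
NCRNA_FEATURES = {"rRNA", "tRNA", "miRNA_locus"}


@dataclass
class ChimeraRecord:
    read_id: str
    mirna_id: str
    orientation: str  # miR_first | miR_last
    mirna_span_in_read: Tuple[int, int]
    target_segment: str
    transcript_id: str
    target_interval: Tuple[int, int]
    ligation_offset: int  # junction position in target-segment coordinates
    region: str
    dup_count: int = 1
    multimapped: bool = False


@dataclass
class Classifier:
    """Holds the reference indexes and classification parameters."""

    mirnas: Dict[str, str]
    transcripts: Dict[str, str]
    annotation: pd.DataFrame
    evalue_max: float = DEFAULT_EVALUE_MAX
    min_target_len: int = MIN_TARGET_LEN
    # minimum nt of the read covered by the miRNA alignment; the explicit
    # counterpart of the long exact word a short-query BLAST search implies,
    # without which chance ~11-mer matches pass the lenient E-value cutoff
    min_mirna_match: int = 16
    mirna_index: KmerIndex = field(init=False)
    tx_index: KmerIndex = field(init=False)
    _feat: Dict[str, List[Tuple[str, int, int]]] = field(init=False)

    def __post_init__(self):
        if not self.mirnas:
            raise ValueError("empty mirnome")
        self.mirna_index = KmerIndex(self.mirnas, WORD_MIRNA)
        self.tx_index = KmerIndex(self.transcripts, WORD_TRANSCRIPT)
        self._feat = {}
        for r in self.annotation.itertuples():
            self._feat.setdefault(r.transcript_id, []).append((r.feature, r.start, r.end))

    # -- operations ---------------------------------------------------------

    def find_mirna_in_read(self, read: ReadRecord) -> Optional[AlignmentHit]:
        hit, _ = best_hit(read.sequence, read.read_id, self.mirna_index, self.evalue_max)
        if hit is not None:
            span = hit.query_interval[1] - hit.query_interval[0]
            if span < self.min_mirna_match:
                return None
        return hit

    def split_read(self, read: ReadRecord, hit: AlignmentHit
                   ) -> Tuple[Optional[str], str, int]:
        """(orientation, target_segment, target_offset_in_read).

        orientation None means miRNA-only (no usable residual) or 'ambiguous'
        is returned via orientation == 'ambiguous'.
        """
        q0, q1 = hit.query_interval
        left = read.sequence[:q0]
        right = read.sequence[q1:]
        if len(left) < self.min_target_len and len(right) < self.min_target_len:
            return None, "", 0
        if len(left) >= self.min_target_len and len(right) >= self.min_target_len:
            return "ambiguous", "", 0
        if len(right) >= len(left):
            if len(left) >= MAX_LINKER_SLACK:
                return "ambiguous", "", 0
            return "miR_first", right, q1
        if len(right) >= MAX_LINKER_SLACK:
            return "ambiguous", "", 0
        return "miR_last", left, 0

    def map_target(self, segment: str) -> Tuple[Optional[AlignmentHit], bool, bool]:
        """(hit, is_ncrna, multimapped) for a target segment."""
        hit, multi = best_hit(
            segment, "", self.tx_index, self.evalue_max, windowed=True
        )
        if hit is None:
            return None, False, False
        feats = {f for f, _, _ in self._feat.get(hit.subject_id, [])}
        return hit, bool(feats & NCRNA_FEATURES), multi

    def annotate_region(self, transcript_id: str, interval: Tuple[int, int]) -> str:
        """Region of the interval midpoint (midpoint rule for spanning hits)."""
        mid = (interval[0] + interval[1]) / 2.0
        for feat, s, e in self._feat.get(transcript_id, []):
            if s <= mid < e and feat in {"5UTR", "CDS", "3UTR"}:
                return feat
        return "NA"

    # -- per-read classification --------------------------------------------

    def classify_read(self, read: ReadRecord
                      ) -> Tuple[str, Optional[ChimeraRecord], Optional[dict]]:
        """Returns (class, chimera_record_or_None, clip_row_or_None)."""
        hit = self.find_mirna_in_read(read)
        if hit is None:
            thit, is_nc, multi = self.map_target(read.sequence)
            if thit is None:
                return "unmapped", None, None
            if is_nc:
                return "ncRNA", None, None
            if multi:
                return "multimapped", None, None
            return "clip", None, dict(
                read_id=read.read_id,
                transcript_id=thit.subject_id,
                start=thit.subject_interval[0],
                end=thit.subject_interval[1],
                dup_count=read.dup_count,
            )
        orientation, segment, seg_off = self.split_read(read, hit)
        if orientation is None:
            return "mirna_only", None, None
        if orientation == "ambiguous":
            return "ambiguous", None, None
        thit, is_nc, multi = self.map_target(segment)
        if thit is None:
            return "unmapped", None, None
        if is_nc:
            return "ncRNA", None, None
        rec = ChimeraRecord(
            read_id=read.read_id,
            mirna_id=hit.subject_id,
            orientation=orientation,
            mirna_span_in_read=hit.query_interval,
            target_segment=segment,
            transcript_id=thit.subject_id,
            target_interval=thit.subject_interval,
            ligation_offset=0 if orientation == "miR_first" else len(segment),
            region=self.annotate_region(thit.subject_id, thit.subject_interval),
            dup_count=read.dup_count,
            multimapped=multi,
        )
        return ("multimapped" if multi else "chimera"), rec, None

    def classify_reads(self, reads: Iterable[ReadRecord]
                       ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int], Dict[str, int]]:
        """Classify a library.

        Returns (chimera table, clip table, class counts, dup-weighted class
        counts). Every read gets exactly one class; record counts sum to the
        input count, while the dup-weighted counts recover raw-read
        composition before PCR-duplicate collapse. Multimapped chimeras are
        included in the table with multimapped=True but counted under
        'multimapped' and excluded from interaction building downstream.
        """
        counts = {c: 0 for c in CLASSES}
        weighted = {c: 0 for c in CLASSES}
        chim_rows = []
        clip_rows = []
        for read in reads:
            cls, rec, clip = self.classify_read(read)
            counts[cls] += 1
            weighted[cls] += read.dup_count
            if rec is not None:
                chim_rows.append(
                    dict(
                        read_id=rec.read_id, mirna_id=rec.mirna_id,
                        orientation=rec.orientation,
                        mirna_read_start=rec.mirna_span_in_read[0],
                        mirna_read_end=rec.mirna_span_in_read[1],
                        target_segment=rec.target_segment,
                        transcript_id=rec.transcript_id,
                        target_start=rec.target_interval[0],
                        target_end=rec.target_interval[1],
                        ligation_offset=rec.ligation_offset,
                        region=rec.region, dup_count=rec.dup_count,
                        multimapped=rec.multimapped,
                    )
                )
            if clip is not None:
                clip_rows.append(clip)
        chim_cols = [
            "read_id", "mirna_id", "orientation", "mirna_read_start", "mirna_read_end",
            "target_segment", "transcript_id", "target_start", "target_end",
            "ligation_offset", "region", "dup_count", "multimapped",
        ]
        clip_cols = ["read_id", "transcript_id", "start", "end", "dup_count"]
        chim = pd.DataFrame(chim_rows, columns=chim_cols)
        clip_df = pd.DataFrame(clip_rows, columns=clip_cols)
        return chim, clip_df, counts, weighted
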