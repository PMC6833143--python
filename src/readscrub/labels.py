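"""Ground-truth percent identity per pileup segment from read-to-reference
alignments (training-time only).

Identity of a read interval is the fraction of its *read* bases aligned as
exact matches to the reference: insertions, mismatches, soft/hard-clipped
and unaligned bases all count in the denominator but never the numerator;
deletions consume no read base and are ignored.  One primary alignment per
read is used (the one with most aligned read bases); unmapped reads get
identity 0 everywhere — chimeric reads therefore score low outside their
primary locus, which is exactly the signal the scrubber is trained on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .pileup import PileupSegment

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignmentRecord:
    """Per-read match mask in original read orientation."""

    read_id: str
    match_mask: np.ndarray | None  # None for unmapped; else bool, len == read length
    aligned_bases: int = 0

    @property
    def is_mapped(self) -> bool:
        return self.match_mask is not None


@dataclass(frozen=True)
class SegmentLabel:
    ref_id: str
    segment_index: int
    base_range: tuple[int, int]
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")


def segment_identity(aln: AlignmentRecord, base_range: tuple[int, int]) -> float:
    """Fraction of read bases in ``base_range`` aligned as exact matches."""
    start, end = base_range
    if end <= start:
        raise ValueError(f"empty base range {base_range}")
    if aln.match_mask is None:
        return 0.0
    if end > len(aln.match_mask):
        raise ValueError(
            f"range {base_range} beyond read length {len(aln.match_mask)}")
    return float(aln.match_mask[start:end].sum()) / (end - start)


def _mask_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    read_id = seg.query_name
    if seg.is_unmapped:
        return AlignmentRecord(read_id, None)
    cigar = seg.cigartuples or []
    length = seg.infer_read_length()
    hard_left = cigar[0][1] if cigar and cigar[0][0] == 5 else 0
    mask = np.zeros(length, dtype=bool)
    aligned = 0
    has_m = any(op == 0 for op, _ in cigar)
    if has_m and seg.has_tag("MD"):
        # MD resolves ambiguous M ops: lowercase reference base = mismatch.
        for qpos, _rpos, refbase in seg.get_aligned_pairs(with_seq=True):
            if qpos is None:
                continue
            if refbase is not None:
                aligned += 1
                if refbase.isupper():
                    mask[hard_left + qpos] = True
    else:
        if has_m:
            logger.warning(
                "read %s: CIGAR uses M without an MD tag; counting M as match",
                read_id)
        pos = 0
        for op, n in cigar:
            if op in (0, 7):          # M / '=' -> match
                mask[pos : pos + n] = True
                aligned += n
                pos += n
            elif op in (1, 4, 8, 5):  # I / S / X / H consume the read
                if op == 8:
                    aligned += n
                pos += n
            # D, N, P consume no read bases
    if seg.is_reverse:
        mask = mask[::-1]
    return AlignmentRecord(read_id, mask, aligned)


def read_sam_alignments(path: str | Path) -> dict[str, AlignmentRecord]:
    """Best primary alignment per read from a SAM file.

    Secondary and supplementary alignments are ignored; if several primary
    records exist for one read, the one with most aligned read bases wins.
    """
    best: dict[str, AlignmentRecord] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                continue
            rec = _mask_from_pysam(seg)
            cur = best.get(rec.read_id)
            if cur is None or rec.aligned_bases > cur.aligned_bases:
                best[rec.read_id] = rec
    return best


def read_paf_alignments(path: str | Path) -> dict[str, AlignmentRecord]:
    """Best alignment per read from PAF records carrying a ``cg:Z:`` tag."""
    best: dict[str, AlignmentRecord] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"line {lineno}: PAF needs >= 12 columns")
            read_id, qlen, qstart, qend, strand = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
            cg = next((x[5:] for x in f[12:] if x.startswith("cg:Z:")), None)
            if cg is None:
                continue
            span = np.zeros(qend - qstart, dtype=bool)
            pos = 0
            aligned = 0
            for n_str, op in _CIGAR_RE.findall(cg):
                n = int(n_str)
                if op in "M=":
                    span[pos : pos + n] = True
                    aligned += n
                    pos += n
                elif op in "IX":
                    if op == "X":
                        aligned += n
                    pos += n
            if pos != qend - qstart:
                raise ValueError(
                    f"line {lineno}: cg consumes {pos} query bases, "
                    f"interval is {qend - qstart}")
            if strand == "-":
                span = span[::-1]
            mask = np.zeros(qlen, dtype=bool)
            mask[qstart:qend] = span
            rec = AlignmentRecord(read_id, mask, aligned)
            cur = best.get(read_id)
            if cur is None or rec.aligned_bases > cur.aligned_bases:
                best[read_id] = rec
    return best


def label_dataset(alignments: Mapping[str, AlignmentRecord],
                  segments: Sequence[PileupSegment]) -> list[SegmentLabel]:
    """One identity label per segment; unaligned reads label 0 everywhere."""
    unmapped = AlignmentRecord("", None)
    return [
        SegmentLabel(
            ref_id=s.ref_id, segment_index=s.segment_index,
            base_range=s.base_range,
            identity=segment_identity(alignments.get(s.ref_id, unmapped),
                                      s.base_range),
        )
        for s in segments
    ]


def write_labels_tsv(labels: Iterable[SegmentLabel], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("ref_id\tsegment_index\tbase_start\tbase_end\tidentity\n")
        for lab in labels:
            handle.write(f"{lab.ref_id}\t{lab.segment_index}\t"
                         f"{lab.base_range[0]}\t{lab.base_range[1]}\t"
                         f"{lab.identity:.6f}\n")


def read_labels_tsv(path: str | Path) -> list[SegmentLabel]:
    labels = []
    with open(path) as handle:
        handle.readline()
        for line in handle:
            rid, idx, b0, b1, ident = line.rstrip("\n").split("\t")
            labels.append(SegmentLabel(rid, int(idx), (int(b0), int(b1)),
                                       float(ident)))
    return labels
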