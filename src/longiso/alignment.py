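"""Spliced-alignment parsing, polyA detection, and read-to-locus routing.

Alignments come from a spliced aligner (e.g. minimap2 in splice mode); this
module never aligns. Each primary record is reduced to its aligned blocks,
the introns between them (N CIGAR operations), soft-clip information and,
when derivable, reference positions of mismatches/indels.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

from .annotation import GenomicInterval, Junction, Locus

logger = logging.getLogger(__name__)

# polyA tail test on the 3' soft clip (polyT head for reverse alignments):
# at least POLYA_MIN_LEN clipped bases with an A fraction of at least
# POLYA_MIN_FRACTION within the first POLYA_SCAN_LEN bases next to the block.
POLYA_MIN_LEN = 6
POLYA_MIN_FRACTION = 0.8
POLYA_SCAN_LEN = 12


class MalformedAlignmentError(ValueError):
    pass


@dataclass
class ReadAlignment:
    """A spliced long-read alignment reduced to reference-space geometry."""

    read_id: str
    chrom: str
    strand: str  # alignment orientation: '+' forward, '-' reverse
    blocks: list[Junction]
    introns: list[Junction]
    left_clip: int = 0
    right_clip: int = 0
    left_clip_seq: str = ""
    right_clip_seq: str = ""
    error_positions: set[int] = field(default_factory=set)
    polya_pos: Optional[int] = None

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def mono_exonic(self) -> bool:
        return not self.introns

    @property
    def intron_chain(self) -> tuple[Junction, ...]:
        return tuple(self.introns)

    def with_blocks(self, blocks: list[Junction]) -> "ReadAlignment":
        """Copy with replaced blocks; introns rederived from the gaps."""
        introns = [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]
        return ReadAlignment(
            self.read_id, self.chrom, self.strand, list(blocks), introns,
            self.left_clip, self.right_clip, self.left_clip_seq,
            self.right_clip_seq, set(self.error_positions), self.polya_pos,
        )


_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_N_OP = 3
_I_OP = 1
_S_OP = 4
_H_OP = 5


def parse_spliced_alignment(record: pysam.AlignedSegment) -> ReadAlignment:
    """Convert a mapped primary pysam record into a :class:`ReadAlignment`.

    M/=/X/D advance the current block; N closes it (an intron); I and S
    consume only query. Consecutive N operations are rejected as malformed.
    """
    if record.is_unmapped or record.is_secondary or record.is_supplementary:
        raise MalformedAlignmentError("record is not a mapped primary alignment")
    if not record.cigartuples:
        raise MalformedAlignmentError("record has no CIGAR")

    blocks: list[Junction] = []
    introns: list[Junction] = []
    pos = record.reference_start
    block_start = pos
    prev_was_n = False
    left_clip = right_clip = 0
    seen_aligned = False
    error_positions: set[int] = set()

    for op, length in record.cigartuples:
        if op in _REF_CONSUMING:
            if op == 2:  # deletion: an error on the reference
                error_positions.update(range(pos, pos + length))
            pos += length
            seen_aligned = True
            prev_was_n = False
        elif op == _N_OP:
            if prev_was_n:
                raise MalformedAlignmentError(
                    f"{record.query_name}: consecutive N CIGAR operations"
                )
            blocks.append((block_start, pos))
            introns.append((pos, pos + length))
            pos += length
            block_start = pos
            prev_was_n = True
        elif op == _I_OP:
            error_positions.add(pos)  # insertion anchored at current ref pos
            prev_was_n = False
        elif op in (_S_OP, _H_OP):
            if seen_aligned:
                right_clip += length
            else:
                left_clip += length
    blocks.append((block_start, pos))

    seq = record.query_sequence or ""
    left_seq = seq[:left_clip] if seq and left_clip else ""
    right_seq = seq[len(seq) - right_clip:] if seq and right_clip else ""

    # mismatch positions from the MD tag when present
    if record.has_tag("MD") and seq:
        try:
            for qpos, rpos, ref_base in record.get_aligned_pairs(
                matches_only=True, with_seq=True
            ):
                if ref_base is not None and ref_base.islower():
                    error_positions.add(rpos)
        except ValueError:  # inconsistent MD: ignore, keep CIGAR-derived errors
            pass

    strand = "-" if record.is_reverse else "+"
    read = ReadAlignment(
        read_id=record.query_name,
        chrom=record.reference_name,
        strand=strand,
        blocks=blocks,
        introns=introns,
        left_clip=left_clip,
        right_clip=right_clip,
        left_clip_seq=left_seq,
        right_clip_seq=right_seq,
        error_positions=error_positions,
    )
    read.polya_pos = detect_polya(read)
    return read


def _tail_fraction(seq: str, base: str) -> bool:
    window = seq[:POLYA_SCAN_LEN]
    if len(window) < POLYA_MIN_LEN:
        return False
    # longest prefix window meeting the fraction, checked at full window
    count = sum(1 for c in window if c.upper() == base)
    return count / len(window) >= POLYA_MIN_FRACTION


def detect_polya(read: ReadAlignment) -> Optional[int]:
    """PolyA evidence from the 3' soft clip; genomic position of the tail.

    Forward alignments carry the tail as an A-rich right clip (position =
    end of the last block); reverse alignments as a T-rich left clip read
    toward the alignment (position = start of the first block). Absence of
    sequence never raises; it simply yields no evidence.
    """
    if read.strand == "+":
        if read.right_clip_seq and _tail_fraction(read.right_clip_seq, "A"):
            return read.end
    else:
        if read.left_clip_seq and _tail_fraction(read.left_clip_seq[::-1], "T"):
            return read.start
    return None


def iter_alignments(path, reference_filename=None):
    """Yield ReadAlignments from a BAM/SAM, counting skipped records."""
    counters = {"parsed": 0, "skipped_unmapped": 0, "skipped_secondary": 0}
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(
        str(path), mode, reference_filename=reference_filename,
        check_sq=False,
    ) as bam:
        for rec in bam:
            if rec.is_unmapped:
                counters["skipped_unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                counters["skipped_secondary"] += 1
                continue
            counters["parsed"] += 1
            yield parse_spliced_alignment(rec)
    logger.info("alignment parsing counters: %s", counters)


def load_alignments(path, reference_filename=None) -> list[ReadAlignment]:
    return list(iter_alignments(path, reference_filename))


def assign_reads_to_loci(
    reads: Iterable[ReadAlignment], loci: list[Locus]
) -> tuple[dict[int, list[ReadAlignment]], list[ReadAlignment]]:
    """Attach each read to every locus its span overlaps (same chromosome).

    Returns (mapping locus-index -> reads, intergenic reads). Reads hitting
    several loci are attached to all of them and resolved by best assignment
    downstream; reads hitting none go to the intergenic bucket used only in
    annotation-free mode.
    """
    # loci are disjoint within one (chrom, strand): binary search per track
    tracks: dict[tuple[str, str], tuple[list[int], list[tuple[int, int, int]]]] = {}
    for idx, locus in enumerate(loci):
        key = (locus.chrom, locus.strand)
        tracks.setdefault(key, ([], []))[1].append(
            (locus.span.start, locus.span.end, idx)
        )
    for starts, spans in tracks.values():
        spans.sort()
        starts.extend(s for s, _, _ in spans)

    assigned: dict[int, list[ReadAlignment]] = {i: [] for i in range(len(loci))}
    intergenic: list[ReadAlignment] = []
    for read in reads:
        hit = False
        for (chrom, _strand), (starts, spans) in tracks.items():
            if chrom != read.chrom:
                continue
            lo = bisect_left(starts, read.start)
            if lo > 0:  # the one locus on this track that may start earlier
                lo -= 1
            for s, e, idx in spans[lo:]:
                if s >= read.end:
                    break
                if e > read.start:
                    assigned[idx].append(read)
                    hit = True
        if not hit:
            intergenic.append(read)
    return assigned, intergenic
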