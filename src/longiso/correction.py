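"""Repair of uniquely assigned spliced alignments.

Four rules, applied per read against its assigned isoform: (1) skipped
short exons are restored from the annotation, (2) junctions within delta of
an annotated junction are snapped onto it, (3) unannotated terminal
microexons are removed, and (4) a remaining unannotated splice site is
substituted by the nearest site of the assigned transcript when it lies
within delta and the alignment shows sequencing errors near that site.
Corrected block coordinates serialize to BED12.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

from .alignment import ReadAlignment
from .annotation import Junction, Transcript
from .assignment import AssignmentParams, match_junction

logger = logging.getLogger(__name__)

ERROR_WINDOW = 10  # bp around a splice site where an error counts as evidence


def _has_error_near(read: ReadAlignment, site: int, window: int = ERROR_WINDOW) -> bool:
    return any(abs(p - site) <= window for p in read.error_positions)


def correct_alignment(
    read: ReadAlignment,
    isoform: Transcript,
    params: AssignmentParams,
) -> ReadAlignment:
    """Return the corrected alignment (the original if correction fails)."""
    delta = params.delta
    chain = list(isoform.intron_chain)
    exon_set = [(e.start, e.end) for e in isoform.exons]

    blocks = list(read.blocks)
    introns = list(read.introns)

    # (3) unannotated terminal microexons
    def _unannotated(block: Junction) -> bool:
        return not any(s < block[1] and block[0] < e for s, e in exon_set)

    if introns and blocks[0][1] - blocks[0][0] <= params.microexon_len and _unannotated(blocks[0]):
        blocks = blocks[1:]
        introns = introns[1:]
    if introns and blocks[-1][1] - blocks[-1][0] <= params.microexon_len and _unannotated(blocks[-1]):
        blocks = blocks[:-1]
        introns = introns[:-1]

    new_chain: list[Junction] = []
    for r in introns:
        # (2) snap to a delta-matching annotated junction
        snapped = None
        best_dev = None
        for j in chain:
            if match_junction(j, r, delta):
                dev = abs(j[0] - r[0]) + abs(j[1] - r[1])
                if best_dev is None or dev < best_dev:
                    snapped, best_dev = j, dev
        if snapped is not None:
            new_chain.append(snapped)
            continue
        # (1) restore a skipped short exon
        restored = False
        for i in range(len(chain) - 1):
            a, b = chain[i], chain[i + 1]
            if (
                b[0] - a[1] <= params.max_skipped_exon_len
                and abs(r[0] - a[0]) <= delta
                and abs(r[1] - b[1]) <= delta
            ):
                new_chain.extend((a, b))
                restored = True
                break
        if restored:
            continue
        # (4) per-site substitution under error evidence
        donors = sorted({j[0] for j in chain})
        acceptors = sorted({j[1] for j in chain})
        s0, s1 = r
        if donors:
            nearest = min(donors, key=lambda d: abs(d - s0))
            if 0 < abs(nearest - s0) <= delta and _has_error_near(read, s0):
                s0 = nearest
        if acceptors:
            nearest = min(acceptors, key=lambda a: abs(a - s1))
            if 0 < abs(nearest - s1) <= delta and _has_error_near(read, s1):
                s1 = nearest
        new_chain.append((s0, s1))

    if not blocks:
        return read
    start, end = blocks[0][0], blocks[-1][1]
    corrected = _blocks_from_chain(start, end, new_chain)
    if corrected is None:
        logger.warning("correction aborted for %s: invalid block layout", read.read_id)
        return read
    return read.with_blocks(corrected)


def _blocks_from_chain(
    start: int, end: int, chain: list[Junction]
) -> Optional[list[Junction]]:
    """Rebuild aligned blocks from a span and an intron chain; None if the
    chain is not strictly increasing inside the span."""
    blocks: list[Junction] = []
    pos = start
    for s, e in chain:
        if s <= pos or e <= s or e >= end:
            return None
        blocks.append((pos, s))
        pos = e
    if pos >= end:
        return None
    blocks.append((pos, end))
    return blocks


def correct_assigned_reads(
    reads_by_id: dict[str, ReadAlignment],
    assignments,
    transcripts_by_id: dict[str, Transcript],
    params: AssignmentParams,
) -> dict[str, ReadAlignment]:
    """Correct every uniquely or conditionally assigned read; other reads
    pass through unchanged. Returns read_id -> (possibly corrected) read."""
    out = dict(reads_by_id)
    for asn in assignments:
        if asn.status not in ("unique", "conditionally_consistent"):
            continue
        read = reads_by_id.get(asn.read_id)
        if read is None or not asn.matched_isoform_ids:
            continue
        isoform = transcripts_by_id[asn.matched_isoform_ids[0]]
        out[asn.read_id] = correct_alignment(read, isoform, params)
    return out


# ---------------------------------------------------------------------------
# BED12


def write_bed12(reads: Iterable[ReadAlignment], path) -> None:
    """One BED12 line per read: name = read_id, score = 0."""
    with open(path, "w") as fh:
        for read in reads:
            start = read.start
            sizes = ",".join(str(e - s) for s, e in read.blocks)
            starts = ",".join(str(s - start) for s, e in read.blocks)
            fh.write(
                f"{read.chrom}\t{start}\t{read.end}\t{read.read_id}\t0\t"
                f"{read.strand}\t{start}\t{read.end}\t0,0,0\t"
                f"{len(read.blocks)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path) -> list[ReadAlignment]:
    """Parse a BED12 file back into block-level ReadAlignments."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            introns = [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]
            reads.append(
                ReadAlignment(name, chrom, strand, blocks, introns)
            )
    return reads
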