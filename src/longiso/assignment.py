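"""Read-to-isoform assignment via delta-tolerant intron-chain matching.

A read and every annotated isoform of its locus are vectorized over the
locus's junction universe (length N) and exon-fragment universe (length M).
Isoform profiles take values in {1, -1}; read profiles additionally use 0
for features outside the alignment span (no information, e.g. truncation).
The distance between a read profile and an isoform profile is the number of
positions where the read value is nonzero and differs from the isoform's.

A read is consistent with an isoform when both distances are zero and the
read shows no unannotated junctions or exonic sequence. Consistency with
one isoform -> unique; with several -> ambiguous; otherwise the read is
inconsistent unless all of its discrepancies are recognized misalignment
artifacts (skipped short exon, small intron shift, terminal microexon), in
which case it is conditionally consistent with the best-matching isoform.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import ReadAlignment
from .annotation import Junction, Locus, Transcript, isoform_profiles

# events that are misalignment artifacts rather than real splicing changes
MISALIGNMENT_EVENTS = {"exon_skip", "intron_shift", "terminal_microexon"}


@dataclass
class AssignmentParams:
    """Matching tolerances; ``delta`` is the per-splice-site slack in bp.

    Defaults follow the data type: 4 bp for PacBio CCS, 6 bp for ONT.
    """

    data_type: str = "ont"
    delta: int = None  # type: ignore[assignment]
    max_skipped_exon_len: int = 30
    microexon_len: int = 15
    shift_window: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data_type not in ("ont", "pacbio_ccs", "pacbio"):
            raise ValueError(f"unknown data type {self.data_type!r}")
        if self.delta is None:
            self.delta = 6 if self.data_type == "ont" else 4
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.shift_window is None:
            self.shift_window = 2 * self.delta


@dataclass
class ReadProfilePair:
    """Junction and exon-fragment profiles of one read in one locus."""

    sj: list[int]
    exon: list[int]
    extra_junctions: list[Junction] = field(default_factory=list)
    has_novel_exonic: bool = False


@dataclass
class ReadAssignment:
    read_id: str
    status: str  # unique | ambiguous | inconsistent | conditionally_consistent
    matched_isoform_ids: list[str]
    events: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)
    locus_index: Optional[int] = None


def match_junction(annot: Junction, obs: Junction, delta: int) -> bool:
    """True iff both endpoint deviations are within delta bp."""
    return abs(annot[0] - obs[0]) <= delta and abs(annot[1] - obs[1]) <= delta


def profile_distance(read_vec: Sequence[int], isoform_vec: Sequence[int]) -> int:
    """Number of informative read positions disagreeing with the isoform."""
    if len(read_vec) != len(isoform_vec):
        raise ValueError("profile length mismatch")
    return sum(1 for r, t in zip(read_vec, isoform_vec) if r != 0 and r != t)


def _nearest_annotated(
    junctions: list[Junction], obs: Junction, delta: int
) -> Optional[int]:
    """Index of the delta-matching annotated junction with minimal total
    endpoint deviation (tie -> lower index), or None."""
    lo = bisect_left(junctions, (obs[0] - delta, -1))
    best = None
    best_dev = None
    for i in range(lo, len(junctions)):
        j = junctions[i]
        if j[0] > obs[0] + delta:
            break
        if match_junction(j, obs, delta):
            dev = abs(j[0] - obs[0]) + abs(j[1] - obs[1])
            if best_dev is None or dev < best_dev:
                best, best_dev = i, dev
    return best


def read_profiles(
    read: ReadAlignment, locus: Locus, params: AssignmentParams
) -> ReadProfilePair:
    """Vectorize a read over the locus junction/fragment universes.

    Junction side: 1 = delta-matched by a read junction (nearest-wins),
    -1 = fully inside the alignment span but unmatched, 0 = outside.
    Exon side: 1 = overlapped by an aligned block (by more than delta bp,
    or covered entirely), -1 = inside the span but only spanned by introns,
    0 = outside. Read junctions matching nothing go to ``extra_junctions``;
    aligned sequence not explained by any annotated exon (beyond delta,
    interior to the span of annotated exons) sets ``has_novel_exonic``.
    """
    delta = params.delta
    n, m = locus.n_junctions, locus.n_fragments
    sj = [0] * n
    extra: list[Junction] = []
    for r in read.introns:
        idx = _nearest_annotated(locus.junctions, r, delta)
        if idx is None:
            extra.append(r)
        else:
            sj[idx] = 1
    for i, j in enumerate(locus.junctions):
        if sj[i] == 0 and j[0] >= read.start and j[1] <= read.end:
            sj[i] = -1

    exon = [0] * m
    for i, (fs, fe) in enumerate(locus.exon_fragments):
        if fe <= read.start or fs >= read.end:
            continue  # outside the alignment span
        best_overlap = 0
        for bs, be in read.blocks:
            ov = min(fe, be) - max(fs, bs)
            if ov > best_overlap:
                best_overlap = ov
        flen = fe - fs
        if best_overlap >= flen or best_overlap > delta:
            exon[i] = 1
        else:
            exon[i] = -1

    # aligned blocks not covered by the annotated exon union (with delta
    # slack at every boundary) indicate unannotated exonic sequence
    has_novel = False
    frags = locus.exon_fragments
    for bs, be in read.blocks:
        uncovered = _uncovered_length(bs, be, frags)
        if uncovered > delta:
            has_novel = True
            break
    return ReadProfilePair(sj, exon, extra, has_novel)


def _uncovered_length(bs: int, be: int, frags: list[Junction]) -> int:
    """Longest contiguous run of [bs, be) not covered by the (sorted,
    disjoint) fragments. Per-gap, not summed: two small overhangs at
    opposite block boundaries (each a delta-bounded alignment artifact)
    must not add up to a novel-exon call."""
    longest = 0
    pos = bs
    lo = bisect_left(frags, (bs, -1))
    if lo > 0 and frags[lo - 1][1] > bs:
        lo -= 1
    for fs, fe in frags[lo:]:
        if fs >= be:
            break
        if fs > pos:
            longest = max(longest, fs - pos)
        pos = max(pos, fe)
    if pos < be:
        longest = max(longest, be - pos)
    return longest


def detect_misalignment_events(
    read: ReadAlignment, isoform: Transcript, params: AssignmentParams
) -> set[str]:
    """Classify discrepancies between a read chain and an isoform chain.

    Recognized artifact patterns: a read junction spanning exactly one
    short annotated exon whose flanking junction endpoints delta-match the
    read junction (exon_skip); a read junction matching an annotated one
    within the shift window but beyond delta (intron_shift); a tiny
    unannotated first/last aligned block (terminal_microexon). Anything
    else yields a real-discrepancy event (novel_junction, intron_retention,
    novel_exon, alt_structure).
    """
    delta = params.delta
    chain = list(isoform.intron_chain)
    events: set[str] = set()
    exon_set = [(e.start, e.end) for e in isoform.exons]

    read_juncs = list(read.introns)
    # terminal microexons: tiny unannotated terminal blocks
    def _unannotated(block: Junction) -> bool:
        return not any(s < block[1] and block[0] < e for s, e in exon_set)

    if read_juncs:
        first, last = read.blocks[0], read.blocks[-1]
        if first[1] - first[0] <= params.microexon_len and _unannotated(first):
            events.add("terminal_microexon")
            read_juncs = read_juncs[1:]
        if read_juncs and last[1] - last[0] <= params.microexon_len and _unannotated(last):
            events.add("terminal_microexon")
            read_juncs = read_juncs[:-1]

    consumed: set[int] = set()
    for r in read_juncs:
        matched = False
        for i, j in enumerate(chain):
            if match_junction(j, r, delta):
                consumed.add(i)
                matched = True
                break
        if matched:
            continue
        # skipped short exon: read junction covers two consecutive annotated
        # junctions around one short exon
        skip = False
        for i in range(len(chain) - 1):
            a, b = chain[i], chain[i + 1]
            exon_len = b[0] - a[1]
            if (
                exon_len <= params.max_skipped_exon_len
                and abs(r[0] - a[0]) <= delta
                and abs(r[1] - b[1]) <= delta
            ):
                consumed.update((i, i + 1))
                events.add("exon_skip")
                skip = True
                break
        if skip:
            continue
        shifted = False
        for i, j in enumerate(chain):
            if match_junction(j, r, params.shift_window):
                consumed.add(i)
                events.add("intron_shift")
                shifted = True
                break
        if shifted:
            continue
        events.add("novel_junction")

    # isoform junctions inside the read span matched by nothing: the read
    # keeps them unspliced
    for i, j in enumerate(chain):
        if i in consumed:
            continue
        if j[0] >= read.start and j[1] <= read.end:
            events.add("intron_retention")

    # aligned sequence outside the isoform's exons; slack is the shift
    # window, since a detected intron shift of up to that size necessarily
    # leaves an equally sized overhang on the adjacent block
    sorted_exons = sorted(exon_set)
    for bs, be in read.blocks:
        cs = max(bs, isoform.start)
        ce = min(be, isoform.end)
        if ce > cs and _uncovered_length(cs, ce, sorted_exons) > params.shift_window:
            events.add("novel_exon")
            break
    return events


def _tss_tes_distance(read: ReadAlignment, isoform: Transcript) -> int:
    return abs(read.start - isoform.start) + abs(read.end - isoform.end)


def classify_read(
    read: ReadAlignment,
    locus: Locus,
    params: AssignmentParams,
    profiles: Optional[ReadProfilePair] = None,
    isoform_profile_cache: Optional[dict] = None,
) -> ReadAssignment:
    """Assign a read to known isoforms of its locus.

    Returns a :class:`ReadAssignment` whose status partitions the read set:
    unique / ambiguous (consistent with 1 / >=2 isoforms), conditionally
    consistent (only artifact discrepancies vs the best isoform), else
    inconsistent (carrying the most similar isoform and its events).
    """
    if not locus.transcripts:
        return ReadAssignment(read.read_id, "inconsistent", [], set())
    if profiles is None:
        profiles = read_profiles(read, locus, params)
    if isoform_profile_cache is None:
        isoform_profile_cache = {}

    clean = not profiles.extra_junctions and not profiles.has_novel_exonic
    consistent: list[Transcript] = []
    distances: dict[str, int] = {}
    for tx in locus.transcripts:
        key = tx.id
        if key not in isoform_profile_cache:
            isoform_profile_cache[key] = isoform_profiles(tx, locus)
        sj_t, ex_t = isoform_profile_cache[key]
        d = profile_distance(profiles.sj, sj_t) + profile_distance(
            profiles.exon, ex_t
        )
        distances[tx.id] = d
        if d == 0 and clean:
            consistent.append(tx)

    gene_ids = sorted({t.gene_id for t in locus.transcripts})
    if len(consistent) == 1:
        return ReadAssignment(
            read.read_id, "unique", [consistent[0].id], set(),
            [consistent[0].gene_id],
        )
    if len(consistent) > 1:
        return ReadAssignment(
            read.read_id, "ambiguous", sorted(t.id for t in consistent),
            set(), sorted({t.gene_id for t in consistent}),
        )

    # no consistent isoform: look for a best match and artifact-only events
    best: Optional[tuple[tuple[int, int, int], Transcript, set[str]]] = None
    for tx in locus.transcripts:
        events = detect_misalignment_events(read, tx, params)
        if not events:
            # profile mismatch with no chain-level explanation (e.g. a
            # mono-exonic read overhanging the isoform)
            events = {"alt_structure"}
        key = (len(events), distances[tx.id], _tss_tes_distance(read, tx))
        if best is None or key < best[0]:
            best = (key, tx, events)
    assert best is not None
    _, best_tx, best_events = best
    if best_events and best_events <= MISALIGNMENT_EVENTS:
        return ReadAssignment(
            read.read_id, "conditionally_consistent", [best_tx.id],
            best_events, [best_tx.gene_id],
        )
    return ReadAssignment(
        read.read_id, "inconsistent", [best_tx.id], best_events,
        [best_tx.gene_id],
    )
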