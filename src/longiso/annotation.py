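"""Gene/transcript data model and GTF I/O.

Internally all coordinates are 0-based half-open; GTF lines (1-based closed)
are converted at the I/O boundary. A :class:`Locus` groups overlapping
same-strand genes and derives the two index spaces every profile vector is
built over: the sorted, deduplicated splice-junction universe (size ``N``)
and the minimal set of disjoint exonic fragments (size ``M``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)


class GenomicInterval(NamedTuple):
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.end - self.start


Junction = tuple[int, int]
"""A splice junction (intron): (donor, acceptor) as a half-open interval."""


@dataclass
class Transcript:
    """An isoform: ordered exons on one strand; introns are the exon gaps."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    source: str = "annotation"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")
        ordered = sorted(self.exons, key=lambda e: (e.start, e.end))
        if ordered != self.exons:
            warnings.warn(f"transcript {self.id}: exons unsorted, normalizing")
            self.exons = ordered
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id}: overlapping exons {a} {b}")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def intron_chain(self) -> tuple[Junction, ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def mono_exonic(self) -> bool:
        return len(self.exons) == 1


@dataclass
class Locus:
    """Processing unit: overlapping same-strand genes merged together.

    ``junctions`` houses the ``N`` sorted annotated splice junctions and
    ``exon_fragments`` the ``M`` elementary exonic intervals; both index the
    profile vectors of reads and isoforms alike.
    """

    chrom: str
    strand: str
    span: GenomicInterval
    transcripts: list[Transcript]
    junctions: list[Junction] = field(default_factory=list)
    exon_fragments: list[Junction] = field(default_factory=list)
    _junction_index: dict[Junction, int] = field(default_factory=dict, repr=False)

    def finalize(self) -> "Locus":
        self.junctions = enumerate_junctions(self)
        self.exon_fragments = split_exon_fragments(self)
        self._junction_index = {j: i for i, j in enumerate(self.junctions)}
        return self

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def n_fragments(self) -> int:
        return len(self.exon_fragments)

    def junction_idx(self, junction: Junction) -> int:
        return self._junction_index[junction]


# ---------------------------------------------------------------------------
# GTF I/O


class GtfParseError(ValueError):
    pass


def _parse_attributes(field9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(gtf_path) -> dict[str, list[Transcript]]:
    """Read a GTF and return transcripts grouped by gene_id.

    Only ``exon`` feature lines are used; ``gene_id`` and ``transcript_id``
    attributes are mandatory. Coordinates are converted from 1-based closed
    to 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: non-integer coordinates"
                ) from exc
            if s < 0 or e <= s:
                raise GtfParseError(f"{gtf_path}:{lineno}: bad interval {start}-{end}")
            attrs = _parse_attributes(attr)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"{gtf_path}:{lineno}: missing gene_id/transcript_id"
                )
            tid = attrs["transcript_id"]
            exons.setdefault(tid, []).append(GenomicInterval(chrom, s, e))
            meta.setdefault(tid, (attrs["gene_id"], chrom, strand))

    genes: dict[str, list[Transcript]] = {}
    for tid, ex in exons.items():
        gene_id, chrom, strand = meta[tid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unsorted GTF exon lines are common
            tx = Transcript(tid, gene_id, chrom, strand, sorted(ex))
        genes.setdefault(gene_id, []).append(tx)
    return genes


def write_gtf(transcripts: Iterable[Transcript], path, extra_attrs=None) -> None:
    """Write transcripts as GTF (1-based closed); see discovery module for
    the model-writing wrapper that adds provenance attributes."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}";'
            for k, v in extra_attrs.get(tx.id, {}).items():
                attrs += f' {k} "{v}";'
            fh.write(
                f"{tx.chrom}\tlongiso\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )
            for ex in tx.exons:
                fh.write(
                    f"{tx.chrom}\tlongiso\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def load_transcript_attribute(gtf_path, key: str) -> dict[str, str]:
    """Collect a per-transcript attribute value (e.g. ``provenance``)."""
    out: dict[str, str] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                continue
            attrs = _parse_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if tid and key in attrs and tid not in out:
                out[tid] = attrs[key]
    return out


# ---------------------------------------------------------------------------
# Locus construction


def build_loci(genes: dict[str, list[Transcript]]) -> list[Locus]:
    """Merge overlapping same-chromosome, same-strand genes into loci.

    Opposite-strand overlaps stay separate; loci are disjoint per strand.
    """
    gene_spans: list[tuple[str, str, int, int, list[Transcript]]] = []
    for txs in genes.values():
        chrom = txs[0].chrom
        strand = txs[0].strand
        start = min(t.start for t in txs)
        end = max(t.end for t in txs)
        gene_spans.append((chrom, strand, start, end, txs))

    gene_spans.sort(key=lambda g: (g[0], g[1], g[2], g[3]))
    loci: list[Locus] = []
    for chrom, strand, start, end, txs in gene_spans:
        if (
            loci
            and loci[-1].chrom == chrom
            and loci[-1].strand == strand
            and start < loci[-1].span.end
        ):
            prev = loci[-1]
            prev.transcripts.extend(txs)
            prev.span = GenomicInterval(chrom, prev.span.start, max(prev.span.end, end))
        else:
            loci.append(
                Locus(chrom, strand, GenomicInterval(chrom, start, end), list(txs))
            )
    for locus in loci:
        locus.finalize()
    return loci


def enumerate_junctions(locus: Locus) -> list[Junction]:
    """Deduplicated annotated junctions sorted by (start, end): index space N."""
    return sorted({j for tx in locus.transcripts for j in tx.intron_chain})


def split_exon_fragments(locus: Locus) -> list[Junction]:
    """Split all annotated exons into the minimal set of M disjoint fragments.

    Fragments are the elementary intervals induced by every exon boundary,
    restricted to positions covered by at least one exon; every annotated
    exon is a union of consecutive fragments.
    """
    exons = sorted(
        {(e.start, e.end) for tx in locus.transcripts for e in tx.exons}
    )
    if not exons:
        return []
    boundaries = sorted({p for s, e in exons for p in (s, e)})
    fragments: list[Junction] = []
    ei = 0
    for s, e in zip(boundaries, boundaries[1:]):
        # advance past exons that end before this elementary interval
        while ei < len(exons) and exons[ei][1] <= s:
            ei += 1
        covered = any(
            ex_s < e and s < ex_e for ex_s, ex_e in exons[ei:] if ex_s < e
        )
        if covered:
            fragments.append((s, e))
    return fragments


def isoform_profiles(transcript: Transcript, locus: Locus):
    """Splice-junction and exon-fragment profiles of an annotated isoform.

    Returns two lists over {1, -1}: position i of the first is 1 iff the
    isoform includes junction i; position i of the second is 1 iff the
    isoform contains exon fragment i.
    """
    if transcript not in locus.transcripts:
        raise ValueError(f"transcript {transcript.id} does not belong to locus")
    chain = set(transcript.intron_chain)
    sj = [1 if j in chain else -1 for j in locus.junctions]
    exon_set = [(e.start, e.end) for e in transcript.exons]
    exon_profile = []
    for fs, fe in locus.exon_fragments:
        inside = any(s <= fs and fe <= e for s, e in exon_set)
        exon_profile.append(1 if inside else -1)
    return sj, exon_profile
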