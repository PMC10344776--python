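"""The discovery core: intron graphs built from spliced read alignments.

Vertices are splice junctions (donor/acceptor coordinate pairs); a directed
edge joins two junctions that are consecutive in at least one read. The
graph is a DAG whose topological order is the genomic order of junctions.
After construction the graph is simplified (tips and bulges created by
inexact splice-site alignment are collapsed onto better-supported nearby
junctions, annotated junctions are never removed), terminal vertices
(transcript starts, ends and clustered polyA positions) are attached, and
transcript models are emitted from paths fully supported by reads
(full-splice matches) passing absolute and relative support cutoffs.

All positional logic is written for the forward strand with polyA tails on
the right; reverse-strand loci are processed on mirrored coordinates and
un-mirrored on output (see :func:`orient_reads` / :func:`unmirror_exons`).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .alignment import ReadAlignment
from .annotation import GenomicInterval, Junction, Transcript

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryParams:
    """Support cutoffs and collapse windows for transcript discovery.

    ONT defaults: at least 5 full-splice-match reads, collapse window 20 bp;
    PacBio: 3 reads, 10 bp. Both share the 2% relative coverage cutoff and
    the 2x support ratio for tip/bulge removal.
    """

    data_type: str = "ont"
    min_fsm_reads: int = None  # type: ignore[assignment]
    rel_coverage_cutoff: float = 0.02
    collapse_window: int = None  # type: ignore[assignment]
    support_ratio: float = 2.0
    delta: int = None  # type: ignore[assignment]
    polya_cluster_radius: int = 12
    report_novel_monoexonic: bool = False

    def __post_init__(self) -> None:
        ont = self.data_type == "ont"
        if self.min_fsm_reads is None:
            self.min_fsm_reads = 5 if ont else 3
        if self.collapse_window is None:
            self.collapse_window = 20 if ont else 10
        if self.delta is None:
            self.delta = 6 if ont else 4
        for name in ("min_fsm_reads", "rel_coverage_cutoff", "collapse_window",
                     "support_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class OrientedRead:
    """A read in locus-oriented (5'->3' increasing) coordinates."""

    read_id: str
    chain: tuple[Junction, ...]
    start: int
    end: int
    polya: Optional[int] = None  # 3' end position when a polyA tail was seen


def orient_reads(
    reads: Iterable[ReadAlignment], locus_strand: str
) -> list[OrientedRead]:
    """Mirror reverse-strand loci so polyA tails always sit on the right."""
    out = []
    for r in reads:
        if locus_strand == "+":
            polya = r.polya_pos if r.polya_pos == r.end else None
            out.append(OrientedRead(r.read_id, tuple(r.introns), r.start, r.end, polya))
        else:
            chain = tuple((-e, -s) for s, e in reversed(r.introns))
            polya = -r.polya_pos if r.polya_pos == r.start else None
            out.append(OrientedRead(r.read_id, chain, -r.end, -r.start, polya))
    return out


def unmirror_exons(exons: Sequence[Junction]) -> list[Junction]:
    return sorted((-e, -s) for s, e in exons)


@dataclass
class IntronGraph:
    """Support-weighted junction DAG with typed terminal vertices."""

    vertices: dict[Junction, int] = field(default_factory=dict)
    edges: dict[tuple[Junction, Junction], int] = field(default_factory=dict)
    collapse_map: dict[Junction, Junction] = field(default_factory=dict)
    # terminal vertices keyed by the junction they attach to
    starts: dict[Junction, int] = field(default_factory=dict)
    ends: dict[Junction, int] = field(default_factory=dict)
    polya_sites: dict[Junction, list[int]] = field(default_factory=dict)

    def successors(self, v: Junction) -> list[Junction]:
        return [b for (a, b) in self.edges if a == v]

    def predecessors(self, v: Junction) -> list[Junction]:
        return [a for (a, b) in self.edges if b == v]

    def substitute(self, chain: Sequence[Junction]) -> tuple[Junction, ...]:
        """Translate a read chain through the collapse map."""
        return tuple(self.collapse_map.get(j, j) for j in chain)

    @property
    def max_coverage(self) -> int:
        return max(self.vertices.values(), default=0)


def build_graph(reads: Iterable[OrientedRead]) -> IntronGraph:
    """Count junction vertices and consecutive-junction edges over reads.

    Mono-exonic reads contribute no vertices. The result is a DAG because
    every edge joins a junction to a strictly downstream one.
    """
    g = IntronGraph()
    for r in reads:
        for j in r.chain:
            g.vertices[j] = g.vertices.get(j, 0) + 1
        for a, b in zip(r.chain, r.chain[1:]):
            g.edges[(a, b)] = g.edges.get((a, b), 0) + 1
    return g


def simplify(
    graph: IntronGraph,
    reads: list[OrientedRead],
    annotated_junctions: set[Junction],
    params: DiscoveryParams,
) -> IntronGraph:
    """Collapse tips and bulges caused by inexact splice-site alignment.

    An unannotated junction is removed when an alternative vertex exists
    with both splice sites within the collapse window and at least
    ``support_ratio`` times its read support. The alternative must share a
    predecessor or successor (the tip/bulge topology); a junction with no
    edges at all may collapse onto any nearby vertex. Removals are recorded
    in the collapse map and the graph is rebuilt from the substituted read
    chains, so no read mass is lost.
    """
    window = params.collapse_window
    preds: dict[Junction, set[Junction]] = defaultdict(set)
    succs: dict[Junction, set[Junction]] = defaultdict(set)
    for a, b in graph.edges:
        succs[a].add(b)
        preds[b].add(a)

    alive = set(graph.vertices)
    collapse: dict[Junction, Junction] = {}
    order = sorted(
        (v for v in graph.vertices if v not in annotated_junctions),
        key=lambda v: (graph.vertices[v], v),
    )
    for v in order:
        if v not in alive:
            continue
        has_edges = bool(preds[v] or succs[v])
        candidates = []
        for u in alive:
            if u == v:
                continue
            if abs(u[0] - v[0]) > window or abs(u[1] - v[1]) > window:
                continue
            if has_edges:
                if not ((preds[v] & preds[u]) or (succs[v] & succs[u])):
                    continue
            candidates.append(u)
        if not candidates:
            continue
        # deterministic best alternative: max support, then leftmost
        alt = max(candidates, key=lambda u: (graph.vertices[u], (-u[0], -u[1])))
        if graph.vertices[alt] >= params.support_ratio * graph.vertices[v]:
            alive.discard(v)
            collapse[v] = alt

    # path-compress chained collapses
    def resolve(j: Junction) -> Junction:
        seen = []
        while j in collapse:
            seen.append(j)
            j = collapse[j]
        for s in seen:
            collapse[s] = j
        return j

    for v in list(collapse):
        resolve(v)

    rebuilt = IntronGraph(collapse_map=collapse)
    for r in reads:
        chain = tuple(collapse.get(j, j) for j in r.chain)
        for j in chain:
            rebuilt.vertices[j] = rebuilt.vertices.get(j, 0) + 1
        for a, b in zip(chain, chain[1:]):
            rebuilt.edges[(a, b)] = rebuilt.edges.get((a, b), 0) + 1
    return rebuilt


def cluster_positions(
    positions: Sequence[int], radius: int
) -> list[tuple[int, int]]:
    """Single-linkage clustering of 1D positions.

    Returns (representative, support) per cluster; the representative is
    the most frequent position, ties broken toward the cluster median and
    then leftward.
    """
    if not positions:
        return []
    counts = Counter(positions)
    uniq = sorted(counts)
    clusters: list[list[int]] = [[uniq[0]]]
    for p in uniq[1:]:
        if p - clusters[-1][-1] <= radius:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for cl in clusters:
        members = [p for p in cl for _ in range(counts[p])]
        median = sorted(members)[len(members) // 2]
        rep = max(cl, key=lambda p: (counts[p], -abs(p - median), -p))
        out.append((rep, sum(counts[p] for p in cl)))
    return out


def attach_terminal_vertices(
    graph: IntronGraph, reads: list[OrientedRead], params: DiscoveryParams
) -> IntronGraph:
    """Attach start, end and clustered polyA terminal vertices.

    For each junction V, only reads whose (collapse-substituted) chain ends
    at V contribute. PolyA positions are clustered and always attached; the
    rightmost non-polyA end P is attached only if (1) V has no outgoing
    edges, or (2) V has a successor (u1, u2) with P > u1 + delta, or (3) V
    has polyA vertices and P lies more than delta beyond all of them.
    Start positions are collected symmetrically without polyA logic.
    """
    delta = params.delta
    ends_at: dict[Junction, list[OrientedRead]] = defaultdict(list)
    starts_at: dict[Junction, list[OrientedRead]] = defaultdict(list)
    for r in reads:
        chain = graph.substitute(r.chain)
        if chain:
            ends_at[chain[-1]].append(r)
            starts_at[chain[0]].append(r)

    succs: dict[Junction, list[Junction]] = defaultdict(list)
    preds: dict[Junction, list[Junction]] = defaultdict(list)
    for a, b in graph.edges:
        succs[a].append(b)
        preds[b].append(a)

    for v in graph.vertices:
        terminating = ends_at.get(v, [])
        polya_positions = [r.polya for r in terminating if r.polya is not None]
        clusters = cluster_positions(polya_positions, params.polya_cluster_radius)
        if clusters:
            graph.polya_sites[v] = [rep for rep, _ in clusters]
        plain_ends = [r.end for r in terminating if r.polya is None]
        if plain_ends:
            p = max(plain_ends)
            # a non-polyA end must lie beyond every adjacent exon start (and
            # beyond all polyA sites) to count as a genuine terminal; an end
            # explainable by any splice continuation is read truncation
            ok = (
                not succs[v]
                or all(p > u1 + delta for u1, _ in succs[v])
                or (clusters and p > max(rep for rep, _ in clusters) + delta)
            )
            if ok:
                graph.ends[v] = p

        starting = starts_at.get(v, [])
        if starting:
            p = min(r.start for r in starting)
            ok = (
                not preds[v]
                or all(p < u2 - delta for _, u2 in preds[v])
            )
            if ok:
                graph.starts[v] = p
    return graph


@dataclass
class TranscriptModel:
    """A predicted isoform with provenance and read support."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Junction]  # locus-oriented; un-mirrored by the caller
    provenance: str  # "novel" | "known"
    supporting_reads: int
    polya_confirmed: bool = False
    reference_id: Optional[str] = None

    @property
    def chain(self) -> tuple[Junction, ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    def to_transcript(self) -> Transcript:
        return Transcript(
            self.id, self.gene_id, self.chrom, self.strand,
            [GenomicInterval(self.chrom, s, e) for s, e in self.exons],
            source="discovered",
        )


def _exons_from_chain(start: int, end: int, chain: Sequence[Junction]):
    exons = []
    pos = start
    for s, e in chain:
        exons.append((pos, s))
        pos = e
    exons.append((pos, end))
    return exons


def construct_paths(
    graph: IntronGraph,
    reads: list[OrientedRead],
    params: DiscoveryParams,
    chrom: str = "",
    strand: str = "+",
    gene_id: str = "novel_gene",
) -> list[TranscriptModel]:
    """Emit candidate models from full-splice-match supported paths.

    A path start -> junction chain -> terminal is a candidate when the
    number of reads whose substituted chain equals the full chain is at
    least ``min_fsm_reads`` and at least ``rel_coverage_cutoff`` of the
    maximum junction support in the graph, and both terminal vertices were
    attached. Terminal positions are then refined per model from the reads
    consistent with it.
    """
    chain_counts: Counter = Counter()
    for r in reads:
        chain = graph.substitute(r.chain)
        if chain:
            chain_counts[chain] += 1

    max_cov = graph.max_coverage
    min_rel = params.rel_coverage_cutoff * max_cov
    models: list[TranscriptModel] = []
    idx = 0
    for chain, n_fsm in sorted(chain_counts.items()):
        if n_fsm < params.min_fsm_reads or n_fsm < min_rel:
            continue
        first, last = chain[0], chain[-1]
        has_start = first in graph.starts
        tes_options = graph.polya_sites.get(last, [])
        has_end = bool(tes_options) or last in graph.ends
        if not (has_start and has_end):
            continue
        start = graph.starts[first]
        end = max(tes_options) if tes_options else graph.ends[last]
        idx += 1
        model = TranscriptModel(
            id=f"{gene_id}.nic.{idx}",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=_exons_from_chain(start, end, chain),
            provenance="novel",
            supporting_reads=n_fsm,
            polya_confirmed=bool(tes_options),
        )
        models.append(refine_terminal_positions(model, reads, graph, params))
    return models


def _is_contiguous_subchain(sub: tuple, full: tuple) -> bool:
    if not sub:
        return True
    n, m = len(sub), len(full)
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def refine_terminal_positions(
    model: TranscriptModel,
    reads: list[OrientedRead],
    graph: IntronGraph,
    params: DiscoveryParams,
) -> TranscriptModel:
    """Re-derive start/end from reads consistent with the model.

    Consistent = the read's substituted chain is a contiguous subchain of
    the model chain. Starts come from consistent reads beginning at the
    first junction; ends from those finishing at the last junction, with
    polyA clusters preferred over plain alignment ends. The intron chain is
    never changed.
    """
    chain = model.chain
    if not chain:
        return model
    starts = []
    polya = []
    plain_ends = []
    for r in reads:
        sub = graph.substitute(r.chain)
        if not sub or not _is_contiguous_subchain(sub, chain):
            continue
        if sub[0] == chain[0]:
            starts.append(r.start)
        if sub[-1] == chain[-1]:
            if r.polya is not None:
                polya.append(r.polya)
            else:
                plain_ends.append(r.end)

    new_start = min(starts) if starts else model.exons[0][0]
    if polya:
        clusters = cluster_positions(polya, params.polya_cluster_radius)
        new_end = max(clusters, key=lambda c: (c[1], c[0]))[0]
        model.polya_confirmed = True
    elif plain_ends:
        new_end = max(plain_ends)
    else:
        new_end = model.exons[-1][1]
    if new_start >= chain[0][0] or new_end <= chain[-1][1]:
        return model  # degenerate refinement; keep prior coordinates
    model.exons = _exons_from_chain(new_start, new_end, chain)
    return model


def add_known_transcripts(
    candidates: list[TranscriptModel],
    unique_counts: dict[str, int],
    polya_confirmed_ids: set[str],
    transcripts: list[Transcript],
    graph: IntronGraph,
    locus_strand: str,
) -> list[TranscriptModel]:
    """Append annotated transcripts meeting the reporting conditions.

    Multi-exon known transcripts need at least one uniquely assigned read
    and a chain fully traversable through the (simplified) graph; known
    mono-exonic transcripts need a unique read and a confirmed polyA site.
    A candidate whose chain equals a known transcript's chain is merged
    into it (the known identity wins).
    """
    def oriented_chain(tx: Transcript) -> tuple[Junction, ...]:
        if locus_strand == "+":
            return tx.intron_chain
        return tuple((-e, -s) for s, e in reversed(tx.intron_chain))

    by_chain = {m.chain: m for m in candidates if m.chain}
    out = []
    reported_chains = set()
    for tx in transcripts:
        n_unique = unique_counts.get(tx.id, 0)
        if n_unique < 1:
            continue
        chain = oriented_chain(tx)
        if tx.mono_exonic:
            if tx.id not in polya_confirmed_ids:
                continue
        else:
            in_graph = all(j in graph.vertices for j in chain) and all(
                (a, b) in graph.edges for a, b in zip(chain, chain[1:])
            )
            if not in_graph:
                continue
        if locus_strand == "+":
            exons = [(e.start, e.end) for e in tx.exons]
        else:
            exons = [(-e.end, -e.start) for e in reversed(tx.exons)]
        model = TranscriptModel(
            id=tx.id, gene_id=tx.gene_id, chrom=tx.chrom, strand=tx.strand,
            exons=exons, provenance="known",
            supporting_reads=n_unique,
            polya_confirmed=tx.id in polya_confirmed_ids,
            reference_id=tx.id,
        )
        out.append(model)
        reported_chains.add(chain)
        if chain in by_chain:
            # merge duplicate novel candidate into the known transcript
            dup = by_chain.pop(chain)
            model.supporting_reads = max(model.supporting_reads, dup.supporting_reads)
            model.exons = dup.exons  # read-derived terminal positions
            model.polya_confirmed = model.polya_confirmed or dup.polya_confirmed

    # relabel remaining candidates that match an unreported annotated chain
    ann_chains = {oriented_chain(tx): tx for tx in transcripts if not tx.mono_exonic}
    final = out
    for m in candidates:
        if m.chain not in by_chain:
            continue
        ref = ann_chains.get(m.chain)
        if ref is not None:
            m.provenance = "known"
            m.reference_id = ref.id
            m.id = ref.id
            m.gene_id = ref.gene_id
        final.append(m)
    return final
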