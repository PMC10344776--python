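"""End-to-end orchestration of the two discovery modes.

Reference-based: assign reads to annotated isoforms, quantify, correct
uniquely assigned alignments, then build/simplify the intron graph per
locus from the corrected reads and report novel + known transcript models.
Annotation-free: cluster reads into loci by alignment span and go straight
to graph construction; every reported model is novel.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import annotation as ann
from . import alignment as aln
from . import assignment as asg
from . import correction as cor
from . import intron_graph as ig
from . import quantification as quant

logger = logging.getLogger(__name__)

_STATUS_RANK = {
    "unique": 0,
    "ambiguous": 1,
    "conditionally_consistent": 2,
    "inconsistent": 3,
}


@dataclass
class PipelineResult:
    models: list[ig.TranscriptModel]
    assignments: list[asg.ReadAssignment] = field(default_factory=list)
    transcript_counts: dict = field(default_factory=dict)
    gene_counts: dict = field(default_factory=dict)
    grouped: Optional[pd.DataFrame] = None
    corrected_reads: dict = field(default_factory=dict)
    outdir: Optional[str] = None

    def models_as_transcripts(self) -> list[ann.Transcript]:
        return [m.to_transcript() for m in self.models]

    @property
    def provenance(self) -> dict[str, str]:
        return {m.id: m.provenance for m in self.models}


def _cluster_reads_into_loci(reads: list[aln.ReadAlignment]):
    """Single-linkage clustering of read spans (any positive gap splits)."""
    reads = sorted(reads, key=lambda r: (r.chrom, r.start, r.end))
    clusters: list[list[aln.ReadAlignment]] = []
    cur_chrom, cur_end = None, -1
    for r in reads:
        if r.chrom != cur_chrom or r.start >= cur_end:
            clusters.append([])
            cur_chrom, cur_end = r.chrom, r.end
        clusters[-1].append(r)
        cur_end = max(cur_end, r.end)
    return clusters


def _majority_strand(reads) -> str:
    n_minus = sum(1 for r in reads if r.strand == "-")
    return "-" if n_minus * 2 > len(reads) else "+"


def _discover_locus(
    reads: list[aln.ReadAlignment],
    strand: str,
    annotated_junctions: set,
    params: ig.DiscoveryParams,
    chrom: str,
    gene_id: str,
) -> tuple[list[ig.TranscriptModel], ig.IntronGraph, list[ig.OrientedRead]]:
    oriented = ig.orient_reads(reads, strand)
    if strand == "-":
        annotated_junctions = {(-e, -s) for s, e in annotated_junctions}
    graph = ig.build_graph(oriented)
    graph = ig.simplify(graph, oriented, annotated_junctions, params)
    graph = ig.attach_terminal_vertices(graph, oriented, params)
    models = ig.construct_paths(
        graph, oriented, params, chrom=chrom, strand=strand, gene_id=gene_id
    )
    # NB: models stay in oriented (possibly mirrored) coordinates; callers
    # un-mirror after known-transcript merging
    return models, graph, oriented


def run_pipeline(
    mode: str,
    bam,
    gtf=None,
    outdir=None,
    data_type: str = "ont",
    assignment_params: Optional[asg.AssignmentParams] = None,
    discovery_params: Optional[ig.DiscoveryParams] = None,
    group_table: Optional[dict] = None,
    seed: int = 0,
) -> PipelineResult:
    """Run transcript discovery (and, with a GTF, assignment/quantification).

    ``mode`` is "reference_based" or "annotation_free". Outputs (models GTF,
    read assignment TSV, corrected BED12, count TSVs) are written under
    ``outdir`` when given; everything is also returned in memory.
    """
    if mode not in ("reference_based", "annotation_free"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "reference_based" and gtf is None:
        raise ValueError("reference_based mode requires a GTF annotation")
    if mode == "annotation_free" and gtf is not None:
        logger.warning("annotation ignored in annotation_free mode")
        gtf = None
    aparams = assignment_params or asg.AssignmentParams(data_type=data_type)
    dparams = discovery_params or ig.DiscoveryParams(data_type=data_type)

    reads = aln.load_alignments(bam)
    result = (
        _run_reference_based(reads, gtf, aparams, dparams, group_table)
        if mode == "reference_based"
        else _run_annotation_free(reads, dparams)
    )

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        result.outdir = outdir
        _write_outputs(result, outdir, mode, aparams, dparams, seed)
    return result


def _run_annotation_free(reads, dparams) -> PipelineResult:
    models: list[ig.TranscriptModel] = []
    for i, cluster in enumerate(_cluster_reads_into_loci(reads)):
        strand = _majority_strand(cluster)
        gene_id = f"NG{i:05d}"
        locus_models, _, _ = _discover_locus(
            cluster, strand, set(), dparams, cluster[0].chrom, gene_id
        )
        if strand == "-":
            for m in locus_models:
                m.exons = ig.unmirror_exons(m.exons)
        models.extend(locus_models)
    return PipelineResult(models=models)


def _run_reference_based(reads, gtf, aparams, dparams, group_table) -> PipelineResult:
    genes = ann.load_annotation(gtf)
    loci = ann.build_loci(genes)
    transcripts_by_id = {t.id: t for txs in genes.values() for t in txs}
    assigned, intergenic = aln.assign_reads_to_loci(reads, loci)

    # classify each read in every overlapping locus; keep the best call
    best: dict[str, tuple[tuple, asg.ReadAssignment, int]] = {}
    profile_store: dict[tuple[int, str], asg.ReadProfilePair] = {}
    iso_caches: dict[int, dict] = {}
    for li, locus_reads in assigned.items():
        locus = loci[li]
        cache = iso_caches.setdefault(li, {})
        for read in locus_reads:
            profiles = asg.read_profiles(read, locus, aparams)
            profile_store[(li, read.read_id)] = profiles
            a = asg.classify_read(read, locus, aparams, profiles, cache)
            a.locus_index = li
            key = (_STATUS_RANK[a.status], len(a.events))
            prev = best.get(read.read_id)
            if prev is None or key < prev[0]:
                best[read.read_id] = (key, a, li)

    assignments = [a for _, a, _ in best.values()]
    assignments.sort(key=lambda a: a.read_id)
    reads_by_id = {r.read_id: r for r in reads}
    corrected = cor.correct_assigned_reads(
        reads_by_id, assignments, transcripts_by_id, aparams
    )

    counts = quant.count_transcripts(assignments)
    expressed = quant.filter_expressed(counts, assignments)
    gene_counts = quant.count_genes(assignments)

    unique_counts: dict[str, int] = {}
    polya_ids: set[str] = set()
    for a in assignments:
        if a.status in quant.UNIQUE_STATUSES:
            tid = a.matched_isoform_ids[0]
            unique_counts[tid] = unique_counts.get(tid, 0) + 1
            r = reads_by_id[a.read_id]
            if r.polya_pos is not None:
                polya_ids.add(tid)

    models: list[ig.TranscriptModel] = []
    read_locus: dict[str, int] = {rid: li for rid, (_, _, li) in best.items()}
    for li, locus in enumerate(loci):
        locus_reads = [
            corrected[r.read_id]
            for r in assigned[li]
            if read_locus.get(r.read_id) == li
        ]
        if not locus_reads:
            continue
        gene_id = locus.transcripts[0].gene_id
        annotated = set(locus.junctions)
        locus_models, graph, oriented = _discover_locus(
            locus_reads, locus.strand, annotated, dparams, locus.chrom, gene_id
        )
        locus_models = ig.add_known_transcripts(
            locus_models, unique_counts, polya_ids, locus.transcripts,
            graph, locus.strand,
        )
        if locus.strand == "-":
            for m in locus_models:
                m.exons = ig.unmirror_exons(m.exons)
        models.extend(locus_models)

    grouped = (
        quant.grouped_counts(assignments, group_table)
        if group_table is not None
        else None
    )
    return PipelineResult(
        models=models,
        assignments=assignments,
        transcript_counts=expressed,
        gene_counts=gene_counts,
        grouped=grouped,
        corrected_reads=corrected,
    )


def _write_outputs(result, outdir, mode, aparams, dparams, seed) -> None:
    extra = {
        m.id: {
            "provenance": m.provenance,
            "reads": m.supporting_reads,
        }
        for m in result.models
    }
    ann.write_gtf(
        sorted(
            result.models_as_transcripts(), key=lambda t: (t.chrom, t.start, t.id)
        ),
        os.path.join(outdir, "transcript_models.gtf"),
        extra_attrs=extra,
    )
    rows = [
        (m.id, m.gene_id, m.provenance, m.supporting_reads,
         ";".join(f"{s}-{e}" for s, e in m.chain))
        for m in sorted(result.models, key=lambda m: m.id)
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "provenance", "reads", "chain"]
    ).to_csv(os.path.join(outdir, "transcript_models.tsv"), sep="\t", index=False)

    if result.assignments:
        pd.DataFrame(
            [
                (a.read_id, a.status, ",".join(a.matched_isoform_ids),
                 ",".join(sorted(a.events)))
                for a in result.assignments
            ],
            columns=["read_id", "status", "isoform_ids", "events"],
        ).to_csv(os.path.join(outdir, "read_assignments.tsv"), sep="\t", index=False)
        quant.write_counts_tsv(
            result.transcript_counts, os.path.join(outdir, "transcript_counts.tsv")
        )
        quant.write_counts_tsv(
            result.gene_counts, os.path.join(outdir, "gene_counts.tsv"), "gene"
        )
        cor.write_bed12(
            sorted(result.corrected_reads.values(), key=lambda r: (r.chrom, r.start, r.read_id)),
            os.path.join(outdir, "corrected_reads.bed"),
        )
        if result.grouped is not None:
            result.grouped.to_csv(
                os.path.join(outdir, "grouped_counts.tsv"), sep="\t"
            )
    with open(os.path.join(outdir, "run_info.log"), "w") as fh:
        fh.write(f"mode={mode}\nseed={seed}\n")
        fh.write(f"delta={aparams.delta}\nmin_fsm_reads={dparams.min_fsm_reads}\n")
        fh.write(f"rel_coverage_cutoff={dparams.rel_coverage_cutoff}\n")
        fh.write(f"collapse_window={dparams.collapse_window}\n")
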