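"""Transcript and gene counting from read assignments.

Uniquely assigned reads (including conditionally consistent reads, which
are corrected toward their isoform) contribute a full count; ambiguous
reads are split uniformly over their k matched isoforms (1/k each);
inconsistent reads are candidate novel isoforms and are excluded from
transcript-level quantification. A transcript enters the expression table
only with at least one uniquely assigned read. Grouped counting (e.g. per
cell barcode) applies the same rule within each read group, so group
columns sum exactly to the ungrouped counts.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional

import pandas as pd

from .annotation import Locus
from .assignment import ReadAssignment, ReadProfilePair

UNIQUE_STATUSES = ("unique", "conditionally_consistent")


def count_transcripts(assignments: Iterable[ReadAssignment]) -> dict[str, float]:
    counts: dict[str, float] = defaultdict(float)
    for asn in assignments:
        if asn.status in UNIQUE_STATUSES:
            counts[asn.matched_isoform_ids[0]] += 1.0
        elif asn.status == "ambiguous":
            k = len(asn.matched_isoform_ids)
            for tid in asn.matched_isoform_ids:
                counts[tid] += 1.0 / k
    return dict(counts)


def count_genes(assignments: Iterable[ReadAssignment]) -> dict[str, float]:
    """Gene counts: per-read mass 1 split over matched genes; inconsistent
    reads contained in a single gene still count at gene level."""
    counts: dict[str, float] = defaultdict(float)
    for asn in assignments:
        genes = asn.gene_ids
        if not genes:
            continue
        if asn.status in UNIQUE_STATUSES or asn.status == "ambiguous":
            for g in set(genes):
                counts[g] += 1.0 / len(set(genes))
        elif asn.status == "inconsistent" and len(set(genes)) == 1:
            counts[genes[0]] += 1.0
    return dict(counts)


def filter_expressed(
    counts: Mapping[str, float], assignments: Iterable[ReadAssignment]
) -> dict[str, float]:
    """Keep only isoforms with at least one uniquely assigned read."""
    unique_ids = {
        a.matched_isoform_ids[0]
        for a in assignments
        if a.status in UNIQUE_STATUSES
    }
    return {tid: c for tid, c in counts.items() if tid in unique_ids}


def grouped_counts(
    assignments: Iterable[ReadAssignment],
    group_table: Mapping[str, str],
) -> pd.DataFrame:
    """Isoform x group count matrix; reads missing from the table go to "NA".

    A read_id mapped to two different groups is an input error.
    """
    assignments = list(assignments)
    seen: dict[str, str] = {}
    for rid, grp in group_table.items():
        if rid in seen and seen[rid] != grp:
            raise ValueError(f"read {rid} assigned to conflicting groups")
        seen[rid] = grp

    by_group: dict[str, list[ReadAssignment]] = defaultdict(list)
    for asn in assignments:
        by_group[group_table.get(asn.read_id, "NA")].append(asn)

    columns = {grp: count_transcripts(asns) for grp, asns in by_group.items()}
    df = pd.DataFrame(columns).fillna(0.0)
    return df.sort_index()[sorted(df.columns)]


def exon_intron_counts(
    read_profiles: Mapping[str, ReadProfilePair], locus: Locus
) -> pd.DataFrame:
    """Inclusion/exclusion read counts per annotated junction and fragment.

    Inclusion counts reads whose profile value is 1, exclusion those with
    -1; zeros (feature outside the alignment) count toward neither. The
    percent-spliced-in of a feature is inclusion / (inclusion + exclusion).
    """
    rows = []
    for i, j in enumerate(locus.junctions):
        inc = sum(1 for p in read_profiles.values() if p.sj[i] == 1)
        exc = sum(1 for p in read_profiles.values() if p.sj[i] == -1)
        rows.append(("intron", locus.chrom, j[0], j[1], inc, exc))
    for i, f in enumerate(locus.exon_fragments):
        inc = sum(1 for p in read_profiles.values() if p.exon[i] == 1)
        exc = sum(1 for p in read_profiles.values() if p.exon[i] == -1)
        rows.append(("exon", locus.chrom, f[0], f[1], inc, exc))
    return pd.DataFrame(
        rows, columns=["feature", "chrom", "start", "end", "inclusion", "exclusion"]
    )


def tpm(counts: Mapping[str, float]) -> dict[str, float]:
    """Per-million scaling of assigned-read counts."""
    total = sum(counts.values())
    if total == 0:
        return {tid: 0.0 for tid in counts}
    return {tid: c / total * 1e6 for tid, c in counts.items()}


def write_counts_tsv(counts: Mapping[str, float], path, feature: str = "transcript") -> None:
    df = pd.DataFrame(
        sorted(counts.items()), columns=[f"{feature}_id", "count"]
    )
    df.to_csv(path, sep="\t", index=False)
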