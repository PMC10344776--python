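"""Deterministic synthetic genomes, annotations and spliced alignments.

The generator emulates the structure of long-read RNA alignments without
performing sequence-level simulation or realignment: reads are emitted
directly as spliced SAM records whose coordinate-level noise (5'/3'
truncation, splice-site shifts, skipped short exons, soft-clipped polyA
tails, mismatches near shifted sites) models the artifacts a spliced
aligner produces on error-prone reads. Every read is listed exactly once
in the accompanying truth table together with its source isoform and the
noise events injected into it.

Loci carry several isoforms sharing their first and last splice junctions
and differing internally (skipped exons, alternative internal junctions),
so every true chain has attachable terminal vertices. Every tenth locus
additionally carries a pair of annotated junctions a few bases apart (a
bulge-forming near pair) to exercise graph simplification. Reverse-strand
loci are emitted with probability one half to exercise coordinate
mirroring.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import pysam

from .annotation import GenomicInterval, Transcript, write_gtf

LOCUS_SPACING = 5_000
LOCI_PER_CHROM = 10
NEAR_PAIR_SHIFT = 14  # annotated near-junction separation: inside the ONT
#                       collapse window (20) but beyond 2*delta (12)


@dataclass
class NoiseModel:
    """Coordinate-level noise injected into simulated alignments."""

    p_shift: float = 0.0          # per junction endpoint
    shift_max: int = 6            # bp, uniform in [-shift_max, shift_max] \ {0}
    p_skip: float = 0.0           # per internal exon <= 30 bp
    max_skippable_exon: int = 30
    p_trunc5: float = 0.0         # probability of 5' truncation
    trunc5_mean: float = 150.0    # geometric mean truncated bases
    p_trunc3: float = 0.0
    trunc3_mean: float = 100.0
    polya_len: int = 30
    p_polya: float = 1.0
    errors_at_shifts: bool = True  # plant a mismatch near each shifted site
    error_rate: float = 0.0       # background per-base mismatch rate

    @classmethod
    def clean(cls) -> "NoiseModel":
        return cls()

    @classmethod
    def moderate(cls) -> "NoiseModel":
        """Moderate ONT-like coordinate noise for protocol benchmarks."""
        return cls(p_shift=0.15, shift_max=6, p_skip=0.3,
                   p_trunc5=0.3, trunc5_mean=120.0,
                   p_trunc3=0.1, trunc3_mean=60.0)


def generate_annotation(
    seed: int,
    n_loci: int = 5,
    isoforms_per_locus: int = 3,
    exon_len_range: tuple[int, int] = (80, 300),
    intron_len_range: tuple[int, int] = (200, 1200),
    short_exon_prob: float = 0.03,
    near_pair_every: int = 10,
) -> tuple[dict[str, str], dict[str, list[Transcript]]]:
    """Random multi-isoform annotation plus a matching random genome.

    Returns (chrom -> sequence, gene_id -> transcripts). Reproducible under
    ``seed``; loci are spaced so their spans never overlap.
    """
    if n_loci <= 0 or isoforms_per_locus <= 0:
        raise ValueError("n_loci and isoforms_per_locus must be positive")
    if exon_len_range[0] > exon_len_range[1] or exon_len_range[0] < 20:
        raise ValueError(f"infeasible exon length range {exon_len_range}")
    if intron_len_range[0] > intron_len_range[1] or intron_len_range[0] < 50:
        raise ValueError(f"infeasible intron length range {intron_len_range}")
    rng = random.Random(seed)
    genome_len: dict[str, int] = {}
    genes: dict[str, list[Transcript]] = {}

    for li in range(n_loci):
        chrom = f"chr{li // LOCI_PER_CHROM + 1}"
        pos = genome_len.get(chrom, 1000)
        n_exons = rng.randint(5, 8)
        exons: list[tuple[int, int]] = []
        for ei in range(n_exons):
            if 0 < ei < n_exons - 1 and rng.random() < short_exon_prob:
                length = rng.randint(20, 30)
            else:
                length = rng.randint(*exon_len_range)
            exons.append((pos, pos + length))
            pos += length + rng.randint(*intron_len_range)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{li:04d}"
        internal = list(range(2, n_exons - 2))  # exons 0,1,-2,-1 are shared

        make_near_pair = (
            near_pair_every
            and li % near_pair_every == 0
            and isoforms_per_locus >= 2
        )
        n_random_variants = isoforms_per_locus - (1 if make_near_pair else 0)
        variants: list[list[tuple[int, int]]] = [list(exons)]
        used = {tuple(exons)}

        def _chain(ex):
            return [(a[1], b[0]) for a, b in zip(ex, ex[1:])]

        existing_junctions = set(_chain(exons))

        def _separable(chain):
            # a new junction with both endpoints near an existing one would
            # be confusable under delta-matching or graph simplification
            for j in chain:
                if j in existing_junctions:
                    continue
                for u in existing_junctions:
                    if abs(j[0] - u[0]) <= 24 and abs(j[1] - u[1]) <= 24:
                        return False
            return True

        attempts = 0
        while len(variants) < n_random_variants and attempts < 50:
            attempts += 1
            ex = list(exons)
            # skip-variants drop only exons clearly above the misalignment
            # artifact class (short skipped exons are indistinguishable from
            # alignment errors by construction of the matcher), so isoform
            # identity never hinges on an artifact-sized difference
            droppable = [
                i for i in internal if exons[i][1] - exons[i][0] > 36
            ]
            if droppable and rng.random() < 0.7:
                drop = rng.sample(droppable, rng.randint(1, min(2, len(droppable))))
                ex = [e for i, e in enumerate(ex) if i not in drop]
            else:
                # alternative acceptor for an internal junction, moved far
                # beyond the collapse window so chains stay separable, and
                # keeping the exon length inside the requested range
                i = rng.randrange(1, len(ex) - 1)
                s, e = ex[i]
                shift = rng.randint(25, 40)
                lo, hi = exon_len_range
                if e - s - shift >= lo:
                    s2 = s + shift
                elif e - s + shift <= hi:
                    s2 = s - shift
                else:
                    s2 = None
                if s2 is not None and ex[i - 1][1] + 50 < s2 < e - 20:
                    ex[i] = (s2, e)
            key = tuple(ex)
            if key not in used and len(ex) >= 2 and _separable(_chain(ex)):
                used.add(key)
                variants.append(ex)
                existing_junctions.update(_chain(ex))

        if make_near_pair:
            # bulge-forming near pair: duplicate a variant, moving the donor
            # of a junction unique to that variant by NEAR_PAIR_SHIFT bp.
            # Uniqueness keeps equal-expression support ratios below the
            # simplification threshold, so both annotated junctions survive
            # annotation-free discovery.
            from collections import Counter

            chains = [
                [(a[1], b[0]) for a, b in zip(ex, ex[1:])] for ex in variants
            ]
            counts = Counter(j for ch in chains for j in set(ch))
            added = False
            for vi, ch in enumerate(chains):
                for ji, j in enumerate(ch):
                    left = variants[vi][ji]
                    if counts[j] == 1 and left[1] - left[0] >= NEAR_PAIR_SHIFT + 30:
                        ex = list(variants[vi])
                        ex[ji] = (left[0], left[1] - NEAR_PAIR_SHIFT)
                        if tuple(ex) not in used:
                            used.add(tuple(ex))
                            variants.append(ex)
                            added = True
                    if added:
                        break
                if added:
                    break

        txs = []
        for vi, ex in enumerate(variants):
            tid = f"{gene_id}.t{vi}"
            txs.append(
                Transcript(
                    tid, gene_id, chrom, strand,
                    [GenomicInterval(chrom, s, e) for s, e in ex],
                )
            )
        genes[gene_id] = txs
        genome_len[chrom] = pos + LOCUS_SPACING

    rng_seq = random.Random(seed + 7919)
    genome = {
        chrom: "".join(rng_seq.choices("ACGT", k=length + 100))
        for chrom, length in genome_len.items()
    }
    return genome, genes


def make_expression_profile(
    seed: int,
    isoforms: list[str],
    distribution: str = "uniform",
    total_reads: int = 1000,
) -> dict[str, int]:
    """Read counts per isoform summing exactly to ``total_reads``."""
    if total_reads < len(isoforms):
        raise ValueError("total_reads must be >= number of isoforms")
    rng = random.Random(seed)
    n = len(isoforms)
    if distribution == "uniform":
        base = total_reads // n
        counts = [base] * n
        for i in range(total_reads - base * n):
            counts[i] += 1
    elif distribution == "lognormal":
        weights = [rng.lognormvariate(0.0, 1.2) for _ in range(n)]
        total_w = sum(weights)
        counts = [max(1, int(w / total_w * total_reads)) for w in weights]
        # repair the sum deterministically
        diff = total_reads - sum(counts)
        order = sorted(range(n), key=lambda i: -weights[i])
        i = 0
        while diff != 0:
            j = order[i % n]
            if diff > 0:
                counts[j] += 1
                diff -= 1
            elif counts[j] > 1:
                counts[j] -= 1
                diff += 1
            i += 1
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return dict(zip(isoforms, counts))


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class _SimRead:
    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    isoform_id: str
    gene_id: str
    mismatch_positions: list[int] = field(default_factory=list)
    shifts: list[tuple[int, int, int, int]] = field(default_factory=list)
    skipped: list[tuple[int, int]] = field(default_factory=list)
    trunc5: int = 0
    trunc3: int = 0
    polya: bool = False


def _truncate(exons, strand, t5, t3):
    """Remove t5/t3 transcript-orientation bases from the exon list."""
    left, right = (t5, t3) if strand == "+" else (t3, t5)
    out = [list(e) for e in exons]
    while left > 0 and out:
        s, e = out[0]
        if e - s <= left:
            left -= e - s
            out.pop(0)
        else:
            out[0][0] = s + left
            left = 0
    while right > 0 and out:
        s, e = out[-1]
        if e - s <= right:
            right -= e - s
            out.pop()
        else:
            out[-1][1] = e - right
            right = 0
    return [tuple(e) for e in out]


def simulate_alignments(
    genome: dict[str, str],
    genes: dict[str, list[Transcript]],
    expression: dict[str, int],
    noise: NoiseModel,
    seed: int,
    sam_path,
    truth_path=None,
) -> pd.DataFrame:
    """Emit noisy spliced SAM records and the per-read truth table.

    The truth table has one row per emitted read: source isoform, injected
    splice-site shifts (old/new junction coordinates), skipped exons,
    truncation lengths and polyA status.
    """
    transcripts = {t.id: t for txs in genes.values() for t in txs}
    unknown = set(expression) - set(transcripts)
    if unknown:
        raise ValueError(f"expression references unknown isoforms: {sorted(unknown)[:3]}")
    rng = random.Random(seed)
    reads: list[_SimRead] = []
    counter = 0
    for tid in sorted(expression):
        tx = transcripts[tid]
        for _ in range(expression[tid]):
            read = _simulate_one(tx, noise, rng, f"read_{counter:07d}")
            if read is not None:
                reads.append(read)
                counter += 1
    reads.sort(key=lambda r: (r.chrom, r.blocks[0][0], r.read_id))
    _write_sam(reads, genome, noise, sam_path)

    rows = []
    for r in reads:
        rows.append({
            "read_id": r.read_id,
            "isoform_id": r.isoform_id,
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "strand": r.strand,
            "start": r.blocks[0][0],
            "end": r.blocks[-1][1],
            "n_introns": len(r.blocks) - 1,
            "shifts": ";".join(
                f"{a},{b}>{c},{d}" for a, b, c, d in r.shifts
            ),
            "skipped_exons": ";".join(f"{s}-{e}" for s, e in r.skipped),
            "trunc5": r.trunc5,
            "trunc3": r.trunc3,
            "polya": int(r.polya),
        })
    truth = pd.DataFrame(rows)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def _simulate_one(
    tx: Transcript, noise: NoiseModel, rng: random.Random, read_id: str
) -> Optional[_SimRead]:
    exons = [(e.start, e.end) for e in tx.exons]
    t5 = t3 = 0
    if noise.p_trunc5 and rng.random() < noise.p_trunc5:
        t5 = min(int(rng.expovariate(1.0 / noise.trunc5_mean)), _tx_len(exons) - 50)
        t5 = max(t5, 0)
    if noise.p_trunc3 and rng.random() < noise.p_trunc3:
        t3 = min(int(rng.expovariate(1.0 / noise.trunc3_mean)),
                 _tx_len(exons) - t5 - 50)
        t3 = max(t3, 0)
    blocks = _truncate(exons, tx.strand, t5, t3)
    if not blocks:
        return None

    skipped: list[tuple[int, int]] = []
    if noise.p_skip:
        kept = [blocks[0]]
        for b in blocks[1:-1]:
            if (b[1] - b[0] <= noise.max_skippable_exon
                    and rng.random() < noise.p_skip):
                skipped.append(b)
            else:
                kept.append(b)
        if len(blocks) > 1:
            kept.append(blocks[-1])
        blocks = kept

    shifts: list[tuple[int, int, int, int]] = []
    mismatches: list[int] = []
    blocks = [list(b) for b in blocks]
    for i in range(len(blocks) - 1):
        orig = (blocks[i][1], blocks[i + 1][0])
        changed = False
        donor, acceptor = orig
        if rng.random() < noise.p_shift:
            s = rng.choice([x for x in range(-noise.shift_max, noise.shift_max + 1) if x])
            if blocks[i][0] + 20 < donor + s < acceptor - 20:
                donor += s
                changed = True
        if rng.random() < noise.p_shift:
            s = rng.choice([x for x in range(-noise.shift_max, noise.shift_max + 1) if x])
            if donor + 20 < acceptor + s < blocks[i + 1][1] - 20:
                acceptor += s
                changed = True
        if changed:
            blocks[i][1] = donor
            blocks[i + 1][0] = acceptor
            shifts.append((orig[0], orig[1], donor, acceptor))
            if noise.errors_at_shifts:
                if donor != orig[0]:
                    mismatches.append(max(blocks[i][0], donor - rng.randint(1, 5)))
                if acceptor != orig[1]:
                    mismatches.append(
                        min(blocks[i + 1][1] - 1, acceptor + rng.randint(1, 5))
                    )
    blocks = [tuple(b) for b in blocks]

    if noise.error_rate:
        for s, e in blocks:
            n_err = sum(1 for _ in range(e - s) if rng.random() < noise.error_rate)
            mismatches.extend(rng.randrange(s, e) for _ in range(n_err))

    # a polyA tail is only observable when the read reaches the 3' end
    polya = bool(noise.polya_len) and t3 == 0 and rng.random() < noise.p_polya
    return _SimRead(
        read_id, tx.chrom, tx.strand, blocks, tx.id, tx.gene_id,
        sorted(set(mismatches)), shifts, skipped, t5, t3, polya,
    )


def _tx_len(exons) -> int:
    return sum(e - s for s, e in exons)


def _write_sam(reads: list[_SimRead], genome: dict[str, str], noise: NoiseModel, path) -> None:
    chroms = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
    }
    tid_of = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment()
            seg.query_name = r.read_id
            seg.reference_id = tid_of[r.chrom]
            seg.reference_start = r.blocks[0][0]
            seg.mapping_quality = 60
            seg.flag = 16 if r.strand == "-" else 0

            ref = genome[r.chrom]
            mset = set(r.mismatch_positions)
            parts = []
            cigar = []
            md_parts = []
            md_run = 0
            nm = 0
            for bi, (s, e) in enumerate(r.blocks):
                if bi > 0:
                    cigar.append((3, s - r.blocks[bi - 1][1]))  # N
                cigar.append((0, e - s))  # M
                block_seq = list(ref[s:e])
                for p in range(s, e):
                    if p in mset:
                        orig = block_seq[p - s].upper()
                        block_seq[p - s] = {"A": "C", "C": "G", "G": "T", "T": "A"}.get(orig, "A")
                        md_parts.append(f"{md_run}{orig}")
                        md_run = 0
                        nm += 1
                    else:
                        md_run += 1
                parts.append("".join(block_seq))
            md_parts.append(str(md_run))

            seq = "".join(parts).upper()
            if r.polya:
                tail = "A" * noise.polya_len
                if r.strand == "+":
                    seq = seq + tail
                    cigar.append((4, noise.polya_len))  # right soft clip
                else:
                    seq = "T" * noise.polya_len + seq
                    cigar.insert(0, (4, noise.polya_len))
            seg.cigartuples = cigar
            seg.query_sequence = seq
            seg.set_tag("MD", "".join(md_parts))
            seg.set_tag("NM", nm)
            out.write(seg)


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_dataset(
    outdir,
    seed: int,
    n_loci: int = 5,
    isoforms_per_locus: int = 3,
    total_reads: int = 1000,
    distribution: str = "uniform",
    noise: Optional[NoiseModel] = None,
    **annotation_kwargs,
):
    """One-call fixture: FASTA + GTF + sorted SAM + truth TSV in outdir."""
    import os

    os.makedirs(outdir, exist_ok=True)
    noise = noise or NoiseModel.clean()
    genome, genes = generate_annotation(
        seed, n_loci, isoforms_per_locus, **annotation_kwargs
    )
    isoforms = [t.id for txs in genes.values() for t in txs]
    expression = make_expression_profile(seed + 1, isoforms, distribution, total_reads)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "sam": os.path.join(outdir, "reads.sam"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(genome, paths["fasta"])
    write_gtf((t for txs in genes.values() for t in txs), paths["gtf"])
    truth = simulate_alignments(
        genome, genes, expression, noise, seed + 2, paths["sam"], paths["truth"]
    )
    return paths, genome, genes, expression, truth
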