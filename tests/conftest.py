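"""Shared fixtures: hand-built loci and generated datasets."""

import pytest

from longiso.alignment import ReadAlignment
from longiso.annotation import GenomicInterval, Transcript, build_loci
from longiso.assignment import AssignmentParams


def make_transcript(tid, exons, gene_id="G1", chrom="chr1", strand="+"):
    return Transcript(
        tid, gene_id, chrom, strand,
        [GenomicInterval(chrom, s, e) for s, e in exons],
    )


def make_read(blocks, read_id="r1", chrom="chr1", strand="+", **kwargs):
    blocks = [tuple(b) for b in blocks]
    introns = [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]
    return ReadAlignment(read_id, chrom, strand, blocks, introns, **kwargs)


@pytest.fixture
def two_isoform_locus():
    """Two isoforms sharing junction (200,300); T1 also splices (350,400).

    Junction universe N=2: [(200,300), (350,400)]; exon fragments M=4:
    [100,200), [300,350), [350,400), [400,500).
    """
    t1 = make_transcript("T1", [(100, 200), (300, 350), (400, 500)])
    t2 = make_transcript("T2", [(100, 200), (300, 500)])
    (locus,) = build_loci({"G1": [t1, t2]})
    return locus


@pytest.fixture
def ont_params():
    return AssignmentParams(data_type="ont")  # delta = 6


@pytest.fixture
def pacbio_params():
    return AssignmentParams(data_type="pacbio_ccs")  # delta = 4
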