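"""Intron graph: construction, simplification, terminals, paths, models."""

import random
from collections import Counter

import pytest

from longiso.intron_graph import (
    DiscoveryParams,
    IntronGraph,
    OrientedRead,
    add_known_transcripts,
    attach_terminal_vertices,
    build_graph,
    cluster_positions,
    construct_paths,
    orient_reads,
    refine_terminal_positions,
    simplify,
)

from .conftest import make_read, make_transcript


def oread(chain, rid="r", start=None, end=None, polya=None):
    chain = tuple(tuple(j) for j in chain)
    if start is None:
        start = (chain[0][0] - 100) if chain else 0
    if end is None:
        end = (chain[-1][1] + 100) if chain else 100
    return OrientedRead(rid, chain, start, end, polya)


def ont() -> DiscoveryParams:
    return DiscoveryParams(data_type="ont")


class TestBuildGraph:
    def test_two_identical_chains(self):
        reads = [oread([(200, 300), (350, 400)], rid=f"r{i}") for i in range(2)]
        g = build_graph(reads)
        assert g.vertices == {(200, 300): 2, (350, 400): 2}
        assert g.edges == {((200, 300), (350, 400)): 2}

    def test_disconnected_single_junction_reads(self):
        g = build_graph([oread([(200, 300)]), oread([(350, 400)])])
        assert len(g.vertices) == 2 and not g.edges

    def test_supports_equal_brute_force_tally(self):
        rng = random.Random(42)
        junctions = [(i * 100, i * 100 + 50) for i in range(1, 9)]
        reads = []
        for i in range(50):
            ln = rng.randint(1, 5)
            start = rng.randint(0, 8 - ln)
            reads.append(oread(junctions[start : start + ln], rid=f"r{i}"))
        g = build_graph(reads)
        v_tally = Counter(j for r in reads for j in r.chain)
        e_tally = Counter(
            (a, b) for r in reads for a, b in zip(r.chain, r.chain[1:])
        )
        assert g.vertices == dict(v_tally)
        assert g.edges == dict(e_tally)

    def test_dag_in_genomic_order(self):
        rng = random.Random(5)
        reads = [
            oread([(s, s + 40), (s + 100, s + 150)], rid=f"r{i}")
            for i, s in enumerate(rng.sample(range(100, 5000, 200), 10))
        ]
        g = build_graph(reads)
        for (a, b) in g.edges:
            assert a[1] <= b[0], "edge must point strictly downstream"


class TestSimplify:
    def test_weak_unannotated_bulge_collapsed(self):
        reads = [oread([(200, 300), (400, 500)], rid=f"a{i}") for i in range(10)]
        reads += [oread([(205, 300), (400, 500)], rid=f"b{i}") for i in range(3)]
        g = build_graph(reads)
        g2 = simplify(g, reads, {(200, 300), (400, 500)}, ont())
        assert (205, 300) not in g2.vertices
        assert g2.collapse_map[(205, 300)] == (200, 300)
        assert g2.vertices[(200, 300)] == 13  # read mass conserved

    def test_support_ratio_below_two_keeps_both(self):
        reads = [oread([(200, 300), (400, 500)], rid=f"a{i}") for i in range(10)]
        reads += [oread([(205, 300), (400, 500)], rid=f"b{i}") for i in range(8)]
        g = build_graph(reads)
        g2 = simplify(g, reads, {(200, 300)}, ont())
        assert (205, 300) in g2.vertices

    def test_no_nearby_alternative_keeps_junction(self):
        reads = [oread([(200, 300), (400, 500)], rid=f"a{i}") for i in range(10)]
        reads += [oread([(250, 330), (400, 500)], rid=f"b{i}") for i in range(3)]
        g = build_graph(reads)
        g2 = simplify(g, reads, {(200, 300)}, ont())
        assert (250, 330) in g2.vertices

    def test_annotated_junction_never_removed(self):
        reads = [oread([(200, 300), (400, 500)], rid=f"a{i}") for i in range(50)]
        reads += [oread([(205, 300), (400, 500)], rid=f"b{i}") for i in range(2)]
        g = build_graph(reads)
        g2 = simplify(g, reads, {(200, 300), (205, 300), (400, 500)}, ont())
        assert (205, 300) in g2.vertices


class TestClusterPositions:
    def test_two_clusters_at_radius(self):
        reps = cluster_positions([1000, 1001, 1002, 1500], radius=12)
        assert len(reps) == 2
        assert reps[0][1] == 3 and reps[1] == (1500, 1)

    def test_representative_is_max_support(self):
        reps = cluster_positions([10, 10, 10, 14], radius=12)
        assert reps == [(10, 4)]

    def test_single_linkage_chains_through_gaps(self):
        reps = cluster_positions([0, 10, 20, 30], radius=12)
        assert len(reps) == 1


class TestAttachTerminals:
    def _graph_with_edge(self):
        reads = [
            oread([(200, 300), (500, 600)], rid=f"a{i}", end=700)
            for i in range(3)
        ]
        return reads

    def test_polya_positions_clustered_and_attached(self):
        reads = [
            oread([(200, 300)], rid=f"r{i}", end=pos, polya=pos)
            for i, pos in enumerate([1000, 1001, 1002, 1500])
        ]
        g = attach_terminal_vertices(build_graph(reads), reads, ont())
        assert len(g.polya_sites[(200, 300)]) == 2

    def test_plain_end_beyond_next_donor_attached(self):
        reads = self._graph_with_edge()
        reads.append(oread([(200, 300)], rid="t", end=510))
        g = attach_terminal_vertices(build_graph(reads), reads, ont())
        assert g.ends[(200, 300)] == 510  # 510 > 500 + 6

    def test_plain_end_within_next_exon_suppressed(self):
        reads = self._graph_with_edge()
        reads.append(oread([(200, 300)], rid="t", end=503))
        g = attach_terminal_vertices(build_graph(reads), reads, ont())
        assert (200, 300) not in g.ends  # 503 <= 506: truncation artifact

    def test_dead_end_vertex_always_gets_terminal(self):
        reads = [oread([(200, 300)], rid="r", end=420)]
        g = attach_terminal_vertices(build_graph(reads), reads, ont())
        assert g.ends[(200, 300)] == 420


class TestConstructPaths:
    def _reads(self, n, chain=((200, 300), (500, 600))):
        return [
            oread(chain, rid=f"r{i}", start=100, end=700, polya=700)
            for i in range(n)
        ]

    @pytest.mark.parametrize("data_type,below,at", [("ont", 4, 5), ("pacbio", 2, 3)])
    def test_absolute_fsm_cutoff_boundary(self, data_type, below, at):
        params = DiscoveryParams(data_type=data_type)
        for n, expected in ((below, 0), (at, 1)):
            reads = self._reads(n)
            g = attach_terminal_vertices(build_graph(reads), reads, params)
            assert len(construct_paths(g, reads, params)) == expected

    def test_relative_coverage_cutoff(self):
        params = ont()
        reads = self._reads(5)
        # an independent heavy chain raises max coverage to 300: 5 < 6
        reads += [
            oread([(1000, 1100), (1300, 1400)], rid=f"h{i}", start=900,
                  end=1500, polya=1500)
            for i in range(300)
        ]
        g = attach_terminal_vertices(build_graph(reads), reads, params)
        chains = {m.chain for m in construct_paths(g, reads, params)}
        assert ((200, 300), (500, 600)) not in chains
        assert ((1000, 1100), (1300, 1400)) in chains

    def test_collapsed_reads_count_toward_fsm(self):
        params = ont()
        reads = self._reads(4)
        reads += [
            oread([(204, 300), (500, 600)], rid="shifted", start=100,
                  end=700, polya=700)
        ]
        g = build_graph(reads)
        g = simplify(g, reads, set(), params)
        g = attach_terminal_vertices(g, reads, params)
        models = construct_paths(g, reads, params)
        assert len(models) == 1 and models[0].supporting_reads == 5


class TestKnownTranscripts:
    def _known(self):
        return make_transcript("K1", [(100, 200), (300, 400)])

    def test_unique_read_and_traversable_chain_reported(self):
        reads = [oread([(200, 300)], rid="r", start=110, end=390)]
        g = build_graph(reads)
        models = add_known_transcripts([], {"K1": 1}, set(), [self._known()], g, "+")
        assert [m.id for m in models] == ["K1"]
        assert models[0].provenance == "known"

    def test_chain_absent_from_graph_not_reported(self):
        g = build_graph([oread([(900, 950)], rid="r")])
        models = add_known_transcripts([], {"K1": 1}, set(), [self._known()], g, "+")
        assert models == []

    def test_no_unique_read_not_reported(self):
        reads = [oread([(200, 300)], rid="r")]
        g = build_graph(reads)
        models = add_known_transcripts([], {}, set(), [self._known()], g, "+")
        assert models == []

    def test_mono_exonic_needs_polya_confirmation(self):
        mono = make_transcript("M1", [(100, 400)])
        g = IntronGraph()
        assert add_known_transcripts([], {"M1": 2}, set(), [mono], g, "+") == []
        models = add_known_transcripts([], {"M1": 2}, {"M1"}, [mono], g, "+")
        assert [m.id for m in models] == ["M1"]


class TestRefineTerminals:
    def test_shared_first_junction_distinct_ends(self):
        """Two chains sharing junction A but ending differently derive each
        TES from their own consistent reads."""
        params = ont()
        a = [
            oread([(200, 300)], rid=f"a{i}", start=100, end=450, polya=450)
            for i in range(6)
        ]
        b = [
            oread([(200, 300), (500, 600)], rid=f"b{i}", start=100, end=800,
                  polya=800)
            for i in range(6)
        ]
        reads = a + b
        g = attach_terminal_vertices(build_graph(reads), reads, params)
        models = construct_paths(g, reads, params)
        ends = {m.chain: m.exons[-1][1] for m in models}
        assert ends[((200, 300),)] == 450
        assert ends[((200, 300), (500, 600))] == 800

    def test_refinement_recomputes_from_consistent_subset(self):
        params = ont()
        reads = [
            oread([(200, 300)], rid=f"r{i}", start=100 - i, end=400 + i,
                  polya=400 + i)
            for i in range(5)
        ]
        g = attach_terminal_vertices(build_graph(reads), reads, params)
        (model,) = construct_paths(g, reads, params)
        refined = refine_terminal_positions(model, reads, g, params)
        assert refined.exons[0][0] == min(r.start for r in reads)
        # polyA ends within the cluster radius collapse to one representative
        assert refined.exons[-1][1] in [r.polya for r in reads]


class TestOrientReads:
    def test_reverse_strand_mirroring_round_trip(self):
        from longiso.intron_graph import unmirror_exons

        read = make_read([(100, 200), (300, 400)], strand="-")
        read.polya_pos = 100
        (o,) = orient_reads([read], "-")
        assert o.chain == ((-300, -200),)
        assert o.polya == -100
        assert unmirror_exons([(-200, -100), (-400, -300)]) == [
            (100, 200), (300, 400)
        ]
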