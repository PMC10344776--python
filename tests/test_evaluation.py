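"""Reduced-annotation protocol, chain matching, metrics, consistency."""

import random

import pytest

from longiso.evaluation import (
    consistency_stats,
    match_transcripts,
    precision_recall_f1,
    reduce_annotation,
    split_known_novel,
    tpm_binned_metrics,
)

from .conftest import make_transcript


def _toy_annotation(n=20):
    txs = {}
    for i in range(n):
        base = i * 10_000
        exons = [(base, base + 200), (base + 500, base + 700), (base + 900, base + 1100)]
        t = make_transcript(f"T{i}", exons, gene_id=f"G{i}")
        txs[t.id] = t
    return txs


class TestReduceAnnotation:
    def test_exact_fraction_removed(self):
        txs = _toy_annotation(100)
        reduced, hidden, kept = reduce_annotation(txs, list(txs), 0.15, seed=0)
        assert len(hidden) == 15 and len(kept) == 85
        assert len(reduced) == 85
        assert hidden.isdisjoint(kept)

    def test_same_seed_is_deterministic(self):
        txs = _toy_annotation(40)
        h1 = reduce_annotation(txs, list(txs), 0.25, seed=11)[1]
        h2 = reduce_annotation(txs, list(txs), 0.25, seed=11)[1]
        assert h1 == h2

    def test_only_expressed_transcripts_eligible(self):
        txs = _toy_annotation(10)
        expressed = [f"T{i}" for i in range(5)]
        reduced, hidden, kept = reduce_annotation(txs, expressed, 0.4, seed=3)
        assert hidden <= set(expressed)
        assert len(hidden) == 2  # round(0.4 * 5)
        # unexpressed transcripts always survive
        assert all(f"T{i}" in reduced for i in range(5, 10))

    def test_invalid_fraction_rejected(self):
        txs = _toy_annotation(4)
        with pytest.raises(ValueError):
            reduce_annotation(txs, list(txs), 1.5, seed=0)


class TestMatchTranscripts:
    def test_identical_chain_different_tes_is_tp(self):
        truth = make_transcript("t", [(0, 100), (200, 300)])
        pred = make_transcript("p", [(10, 100), (200, 500)])
        res = match_transcripts([pred], [truth])
        assert res.counts == (1, 0, 0)

    def test_missing_junction_is_fp_and_fn(self):
        truth = make_transcript("t", [(0, 100), (200, 300), (400, 500)])
        pred = make_transcript("p", [(0, 100), (200, 500)])
        res = match_transcripts([pred], [truth])
        assert res.counts == (0, 1, 1)

    def test_mono_exonic_reciprocal_overlap(self):
        truth = make_transcript("t", [(0, 1000)])
        good = make_transcript("p1", [(100, 1000)])  # overlap 0.9 / 1.0
        bad = make_transcript("p2", [(600, 2000)])
        assert match_transcripts([good], [truth]).counts == (1, 0, 0)
        assert match_transcripts([bad], [truth]).counts == (0, 1, 1)

    def test_random_sets_equal_all_pairs_oracle(self):
        rng = random.Random(99)
        def random_tx(tid):
            base = rng.randrange(0, 40) * 1000
            n = rng.randint(2, 4)
            exons, pos = [], base
            for _ in range(n):
                exons.append((pos, pos + 100))
                pos += 100 + rng.choice([200, 300])
            return make_transcript(tid, exons)

        truth = [random_tx(f"t{i}") for i in range(50)]
        preds = [random_tx(f"p{i}") for i in range(50)]
        res = match_transcripts(preds, truth)
        truth_chains = {}
        for t in truth:
            truth_chains.setdefault((t.chrom, t.intron_chain), []).append(t.id)
        expected_tp = 0
        used = set()
        for p in preds:
            for tid in truth_chains.get((p.chrom, p.intron_chain), []):
                if tid not in used:
                    used.add(tid)
                    expected_tp += 1
                    break
        assert len(res.tp) == expected_tp
        assert len(res.fp) == 50 - expected_tp
        assert len(res.fn) == 50 - expected_tp

    def test_tp_matching_is_symmetric(self):
        a = [make_transcript("a", [(0, 100), (200, 300)])]
        b = [make_transcript("b", [(5, 100), (200, 290)])]
        assert len(match_transcripts(a, b).tp) == len(match_transcripts(b, a).tp)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (8, 2, 2, (0.8, 0.8, 0.8)),
            (0, 5, 5, (0.0, 0.0, 0.0)),
            (5, 0, 5, (1.0, 0.5, 2 / 3)),
        ],
    )
    def test_examples(self, tp, fp, fn, expected):
        assert precision_recall_f1(tp, fp, fn) == pytest.approx(expected)

    def test_bounded_in_unit_interval(self):
        rng = random.Random(1)
        for _ in range(100):
            p, r, f1 = precision_recall_f1(
                rng.randint(0, 20), rng.randint(0, 20), rng.randint(0, 20)
            )
            assert 0 <= p <= 1 and 0 <= r <= 1 and 0 <= f1 <= 1
            m = min(p, r)
            assert f1 <= 2 * m / (1 + m) + 1e-12 if m else f1 == 0


class TestSplitKnownNovel:
    def test_provenance_tags_respected(self):
        t = make_transcript("a", [(0, 100), (200, 300)])
        known, novel = split_known_novel([t], {"a": "known"})
        assert known and not novel

    def test_untagged_falls_back_to_chain_lookup(self):
        t = make_transcript("a", [(0, 100), (200, 300)])
        ref = {"r": make_transcript("r", [(5, 100), (200, 290)])}
        known, novel = split_known_novel([t], {}, reduced=ref)
        assert known and not novel
        other = make_transcript("b", [(0, 100), (250, 300)])
        known, novel = split_known_novel([other], {}, reduced=ref)
        assert novel and not known


class TestTpmBins:
    def _match(self):
        truth = [make_transcript(f"t{i}", [(i * 1000, i * 1000 + 100),
                                           (i * 1000 + 200, i * 1000 + 300)])
                 for i in range(4)]
        preds = [make_transcript(f"p{i}", [(i * 1000, i * 1000 + 100),
                                           (i * 1000 + 200, i * 1000 + 300)])
                 for i in range(3)]
        fp = make_transcript("px", [(50_000, 50_100), (50_200, 50_300)])
        return match_transcripts(preds + [fp], truth)

    def test_recall_uses_true_tpm_and_precision_reported_tpm(self):
        m = self._match()
        true_tpm = {f"t{i}": 5.0 for i in range(4)}
        reported = {f"p{i}": 5.0 for i in range(3)} | {"px": 500.0}
        df = tpm_binned_metrics(m, true_tpm, reported, [0, 100, 1000])
        low, high = df.iloc[0], df.iloc[1]
        assert low.recall == pytest.approx(3 / 4)
        assert low.precision == 1.0  # the FP sits in the high bin only
        assert high.precision == 0.0 and high.fp == 1

    def test_single_bin_recovers_global_metrics(self):
        m = self._match()
        true_tpm = {f"t{i}": 1.0 for i in range(4)}
        reported = {f"p{i}": 1.0 for i in range(3)} | {"px": 1.0}
        df = tpm_binned_metrics(m, true_tpm, reported, [0, 10])
        tp, fp, fn = m.counts
        p, r, _ = precision_recall_f1(tp, fp, fn)
        assert df.iloc[0].precision == pytest.approx(p)
        assert df.iloc[0].recall == pytest.approx(r)


class TestConsistencyStats:
    def test_identical_chain_supported_by_all_others(self):
        t = [(0, 100), (200, 300)]
        sets = {f"tool{i}": [make_transcript(f"x{i}", t)] for i in range(3)}
        stats = consistency_stats(sets)
        for st in stats.values():
            assert st["supported_by"][2] == 1

    def test_private_chain_supported_by_none(self):
        sets = {
            "a": [make_transcript("x", [(0, 100), (200, 300)])],
            "b": [make_transcript("y", [(0, 100), (250, 300)])],
        }
        stats = consistency_stats(sets)
        assert stats["a"]["supported_by"][0] == 1

    def test_missed_by_one_tool_counted(self):
        t = [(0, 100), (200, 300)]
        sets = {
            "a": [make_transcript("xa", t)],
            "b": [make_transcript("xb", t)],
            "c": [make_transcript("xc", [(0, 100), (250, 300)])],
        }
        stats = consistency_stats(sets)
        assert stats["c"]["missed_only_here"] == 1

    def test_random_sets_equal_brute_force(self):
        rng = random.Random(3)
        chains = [((i * 1000, i * 1000 + 100), (i * 1000 + 300, i * 1000 + 400))
                  for i in range(10)]
        sets = {}
        for name in "abc":
            picked = rng.sample(chains, rng.randint(2, 8))
            sets[name] = [
                make_transcript(f"{name}{k}", [(c[0][0] - 50, c[0][0]),
                                               (c[0][1], c[1][0]),
                                               (c[1][1], c[1][1] + 50)])
                for k, c in enumerate(picked)
            ]
        stats = consistency_stats(sets)
        chain_sets = {
            n: {(t.chrom, t.intron_chain) for t in txs} for n, txs in sets.items()
        }
        for n in sets:
            others = [chain_sets[o] for o in sets if o != n]
            expected = {i: 0 for i in range(3)}
            for c in chain_sets[n]:
                expected[sum(c in o for o in others)] += 1
            assert stats[n]["supported_by"] == expected
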