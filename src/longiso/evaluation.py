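"""Benchmarking protocol for transcript discovery.

A fraction of expressed isoforms is hidden from the annotation (the "true
novel" set); discovery then runs against the reduced annotation and its
output is split into known and novel predictions, each scored against its
baseline by intron-chain identity (multi-exon; the gffcompare "=" match
class) or reciprocal overlap (mono-exonic). Precision/recall can further
be binned by TPM, and prediction sets from several tools can be compared
for mutual support.
"""

from __future__ import annotations

import random
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import Transcript

MONO_RECIPROCAL_OVERLAP = 0.8


def _chain_key(tx: Transcript):
    return (tx.chrom, tx.intron_chain)


def reduce_annotation(
    transcripts: Mapping[str, Transcript],
    expressed_ids: Sequence[str],
    fraction: float,
    seed: int,
) -> tuple[dict[str, Transcript], set[str], set[str]]:
    """Hide round(fraction * n_expressed) expressed isoforms at random.

    Returns (reduced annotation, hidden "true novel" ids, kept "true known"
    ids). Genes whose only isoform is hidden disappear from the reduced
    annotation entirely.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    missing = [t for t in expressed_ids if t not in transcripts]
    if missing:
        raise ValueError(f"expressed ids not in annotation: {missing[:3]}")
    rng = random.Random(seed)
    expressed = sorted(expressed_ids)
    n_hide = round(fraction * len(expressed))
    hidden = set(rng.sample(expressed, n_hide))
    kept = set(expressed) - hidden
    reduced = {tid: tx for tid, tx in transcripts.items() if tid not in hidden}
    return reduced, hidden, kept


@dataclass
class MatchResult:
    tp: list[tuple[str, str]]  # (prediction id, truth id)
    fp: list[str]
    fn: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.tp), len(self.fp), len(self.fn)


def _reciprocal_overlap(a: Transcript, b: Transcript) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def match_transcripts(
    predicted: Iterable[Transcript], truth: Iterable[Transcript]
) -> MatchResult:
    """Match predictions to truth transcripts.

    Multi-exon: identical intron chain on the same chromosome (terminal
    positions ignored). Mono-exonic: reciprocal overlap >= 0.8 on the same
    chromosome and strand. Each prediction matches at most one truth
    transcript and vice versa; unmatched truth transcripts are FN.
    """
    predicted = list(predicted)
    truth = list(truth)
    truth_by_chain: dict = defaultdict(list)
    mono_truth = []
    for t in truth:
        if t.mono_exonic:
            mono_truth.append(t)
        else:
            truth_by_chain[_chain_key(t)].append(t)

    matched_truth: set[str] = set()
    tp: list[tuple[str, str]] = []
    fp: list[str] = []
    for p in predicted:
        hit: Optional[Transcript] = None
        if p.mono_exonic:
            best = 0.0
            for t in mono_truth:
                if t.id in matched_truth or t.chrom != p.chrom or t.strand != p.strand:
                    continue
                ro = _reciprocal_overlap(p, t)
                if ro >= MONO_RECIPROCAL_OVERLAP and ro > best:
                    hit, best = t, ro
        else:
            for t in truth_by_chain.get(_chain_key(p), []):
                if t.id not in matched_truth:
                    hit = t
                    break
        if hit is None:
            fp.append(p.id)
        else:
            matched_truth.add(hit.id)
            tp.append((p.id, hit.id))
    fn = [t.id for t in truth if t.id not in matched_truth]
    return MatchResult(tp, fp, fn)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = harmonic mean; 0 on empty."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def split_known_novel(
    predictions: Iterable[Transcript],
    provenance: Mapping[str, str],
    reduced: Optional[Mapping[str, Transcript]] = None,
) -> tuple[list[Transcript], list[Transcript]]:
    """Split predictions by their known/novel provenance attribute.

    Predictions without a provenance tag fall back to chain comparison
    against the reduced annotation: chains present there are known.
    """
    known, novel = [], []
    reduced_chains = (
        {_chain_key(t) for t in reduced.values() if not t.mono_exonic}
        if reduced
        else set()
    )
    for p in predictions:
        tag = provenance.get(p.id)
        if tag is None:
            tag = "known" if _chain_key(p) in reduced_chains else "novel"
        (known if tag == "known" else novel).append(p)
    return known, novel


def tpm_binned_metrics(
    match: MatchResult,
    true_tpm: Mapping[str, float],
    reported_tpm: Mapping[str, float],
    bin_edges: Sequence[float],
):
    """Per-TPM-bin precision and recall.

    Recall bins truth transcripts by their simulated TPM; precision bins
    predictions by reported TPM (a false prediction has no true TPM). The
    asymmetry is inherent to the protocol. Bin i covers
    [bin_edges[i], bin_edges[i+1]).
    """
    import pandas as pd

    def bin_of(v: float) -> Optional[int]:
        for i in range(len(bin_edges) - 1):
            if bin_edges[i] <= v < bin_edges[i + 1]:
                return i
        return None

    n_bins = len(bin_edges) - 1
    tp_r = [0] * n_bins
    fn_r = [0] * n_bins
    tp_p = [0] * n_bins
    fp_p = [0] * n_bins
    matched_truth = {t for _, t in match.tp}
    pred_of_truth = {t: p for p, t in match.tp}
    for tid, tpm in true_tpm.items():
        b = bin_of(tpm)
        if b is None:
            continue
        if tid in matched_truth:
            tp_r[b] += 1
        else:
            fn_r[b] += 1
    for pid, _ in match.tp:
        b = bin_of(reported_tpm.get(pid, 0.0))
        if b is not None:
            tp_p[b] += 1
    for pid in match.fp:
        b = bin_of(reported_tpm.get(pid, 0.0))
        if b is not None:
            fp_p[b] += 1

    rows = []
    for i in range(n_bins):
        prec = tp_p[i] / (tp_p[i] + fp_p[i]) if tp_p[i] + fp_p[i] else 0.0
        rec = tp_r[i] / (tp_r[i] + fn_r[i]) if tp_r[i] + fn_r[i] else 0.0
        rows.append(
            (bin_edges[i], bin_edges[i + 1], tp_p[i], fp_p[i], prec,
             tp_r[i], fn_r[i], rec)
        )
    return pd.DataFrame(
        rows,
        columns=["tpm_lo", "tpm_hi", "tp_precision", "fp", "precision",
                 "tp_recall", "fn", "recall"],
    )


def consistency_stats(
    tool_sets: Mapping[str, Iterable[Transcript]],
) -> dict[str, dict]:
    """Cross-tool support histogram by intron-chain identity.

    For each tool, counts its transcripts supported by 0..k-1 other tools,
    plus the number of chains reported by every other tool but missed by
    this one.
    """
    if len(tool_sets) < 2:
        raise ValueError("need at least two prediction sets")
    chains = {
        name: {_chain_key(t) for t in txs if not t.mono_exonic}
        for name, txs in tool_sets.items()
    }
    out: dict[str, dict] = {}
    names = list(chains)
    for name in names:
        others = [chains[o] for o in names if o != name]
        hist = {i: 0 for i in range(len(names))}
        for c in chains[name]:
            support = sum(1 for o in others if c in o)
            hist[support] += 1
        missed = set.intersection(*others) - chains[name] if others else set()
        out[name] = {"supported_by": hist, "missed_only_here": len(missed)}
    return out
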