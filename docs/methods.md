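# Methods

This note documents the models and procedures implemented in `longiso`,
the parameter defaults and the reasons behind them, the design choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Coordinate conventions

All internal coordinates are 0-based half-open. GTF (1-based closed) and
BED12 (0-based half-open) are converted at the I/O boundary only. A splice
junction (intron) is the ordered pair *(donor, acceptor)* written as the
half-open interval between two aligned blocks; an intron chain is the
ordered tuple of a transcript's junctions. Two transcripts with identical
chains are the same isoform for matching purposes regardless of terminal
positions.

Loci are the processing unit: genes overlapping on the same chromosome and
strand are merged (so a read is scored against all candidate isoforms at
once); opposite-strand overlaps stay separate. All strand-dependent logic
(polyA on the right, terminal conditions) is written for the forward
strand; reverse-strand loci are processed on mirrored coordinates
(*x → −x*) and un-mirrored on output, giving a single code path.

## Read-to-isoform assignment

For a locus, the annotated junctions are sorted and indexed 1..N and all
annotated exons are split into the minimal set of M disjoint elementary
fragments. An isoform is the pair of ±1 vectors over these universes; a
read additionally uses 0 for features outside its alignment span (no
information, typically truncation). The profile distance counts positions
where the read is informative and disagrees.

Junction matching tolerates a per-splice-site deviation Δ (default 6 bp
ONT, 4 bp PacBio CCS; configurable). Each read junction matches at most
one annotated junction — the one with the smallest total endpoint
deviation, ties to the lower index. Two interpretive choices in the read
profile are deliberate and load-bearing:

* An unmatched annotated junction is marked −1 ("spanned unspliced") only
  when it lies **entirely** inside the alignment span; a junction partially
  overlapping a truncated read end stays 0. Otherwise truncation would
  manufacture disagreements.
* An exon fragment counts as overlapped (1) only when an aligned block
  covers it entirely or overlaps it by **more than Δ** bases. A splice-site
  shift of ≤ Δ shifts block boundaries by the same amount and must not flip
  fragment states.
* Unannotated exonic sequence is flagged from the longest *contiguous*
  uncovered run of a block (not the summed uncovered length): two Δ-bounded
  overhangs at opposite block boundaries are alignment noise, a single long
  uncovered run is a novel exon.

Consistency = both distances zero and no unannotated junctions/exonic
sequence. One consistent isoform → `unique`; several → `ambiguous`. For
inconsistent reads, discrepancies against each isoform are classified:
`exon_skip` (a read junction spanning one annotated exon ≤ 30 bp whose
flanking junctions Δ-match the read junction's endpoints), `intron_shift`
(a junction matching within the shift window, default 2Δ, but beyond Δ),
`terminal_microexon` (an unannotated terminal block ≤ 15 bp), and the
non-artifact classes `novel_junction`, `intron_retention`, `novel_exon`,
`alt_structure`. If the best-matching isoform — ranked by (event count,
profile distance, terminal-position distance) — shows only artifact
events, the read is `conditionally_consistent` with it. The "short" size
thresholds are not fixed by theory; 30/15 bp are configurable defaults.

Mono-exonic reads carry no junction signal; they are consistent with any
isoform whose exons cover them (hence usually ambiguous).

## Alignment correction

Uniquely and conditionally assigned reads are corrected against their
isoform: skipped short exons are re-inserted from the annotation;
junctions within Δ of an annotated junction are snapped onto it;
unannotated terminal microexons are removed; a remaining unannotated
splice site is substituted by the nearest site of the assigned transcript
only if within Δ **and** the alignment shows a mismatch/indel within 10 bp
of the site (error evidence from the MD tag and D/I CIGAR operations;
without evidence the substitution is skipped). A correction that would
produce an invalid block layout is abandoned and the original alignment
kept. Correction is idempotent. Corrected coordinates are written as BED12
and the corrected reads feed graph construction.

## Quantification

Unique (including conditionally consistent) reads add 1.0 to their
isoform; an ambiguous read over k isoforms adds 1/k to each — a uniform
split, chosen over an EM scheme for transparency; total read mass is
conserved exactly. Inconsistent reads are excluded from transcript counts
but still count at gene level when they fall inside a single gene. A
transcript enters the expression table only with ≥ 1 unique read. Grouped
counting applies the same rules within each read group, so group columns
sum exactly to the global counts. Per-junction and per-fragment
inclusion/exclusion counts (profile value 1 / −1; zeros excluded) support
percent-spliced-in analyses.

## Transcript discovery

**Graph.** Vertex support = number of alignments containing the junction;
edge support = number containing the consecutive pair. Mono-exonic reads
contribute no vertices.

**Simplification.** Unannotated junctions are visited in increasing
(support, coordinate) order. Candidate alternatives are vertices sharing a
predecessor or successor (the tip/bulge topology); a junction with no
edges at all — only observable in single-junction reads — may use any
vertex within the window. An alternative qualifies with both splice sites
within the collapse window (20 bp ONT / 10 bp PacBio) and support ≥ 2×
that of the junction being tested; among qualifying alternatives the
best-supported (tie: leftmost) wins. Removals are recorded in a collapse
map (path-compressed), and the graph is rebuilt from the substituted read
chains, so read mass is conserved and reads through removed junctions
still traverse the graph.

**Terminals.** For each junction V, reads whose (substituted) chain ends
at V contribute: polyA positions are clustered by single linkage at radius
12 bp (representative: most frequent position, ties toward the cluster
median, then leftmost) and attached as terminal vertices. The rightmost
non-polyA end P attaches only if V has no outgoing edges, or P exceeds
**every** successor donor by more than Δ, or P exceeds every polyA site by
more than Δ. The "every" is deliberate: an end explainable by any splice
continuation is indistinguishable from truncation, and with several
alternative acceptors upstream the analogous any-reading demonstrably
admits truncation artifacts as spurious alternative starts. Start
positions mirror this logic without polyA.

**Paths.** Candidate models are the distinct substituted read chains with
at least `min_fsm_reads` full-splice matches (5 ONT / 3 PacBio — a read
supports a chain only if its whole chain equals it), at least 2% of the
locus's peak junction support, and attached terminals at both ends.
Terminal positions are then refined per model from the reads consistent
with it (contiguous sub-chains), preferring the strongest polyA cluster
for the 3′ end. With an annotation, known multi-exon transcripts with ≥ 1
uniquely assigned read and a chain fully traversable through the
simplified graph are added (known mono-exonic transcripts additionally
require polyA evidence on a uniquely assigned read); a novel candidate
with the same chain as a reported known transcript merges into it, the
known identity winning. The 2% relative cutoff applies to novel candidates
only. Novel mono-exonic models are not emitted by default.

In annotation-free mode, loci are single-linkage clusters of read spans
(any positive gap splits), locus strand is the majority alignment strand,
and all models are novel.

## PolyA detection

The paper-level pipeline assumes polyA evidence exists per read; the
detector here calls a tail when the 3′ soft clip (A-rich on the right for
forward alignments, T-rich on the left, read inward, for reverse) has ≥ 6
clipped bases with ≥ 80% A within the first 12 bases adjacent to the
alignment. Missing sequence yields "no evidence", never an error.

## Evaluation protocol

`reduce_annotation` hides round(fraction × |expressed|) expressed isoforms
uniformly at random (seeded); discovery then runs against the reduced GTF
and its output is split by the provenance attribute (fallback: chain
lookup). Matching follows intron-chain identity for multi-exon transcripts
(terminal positions ignored — the "=" class of standard transcript
comparison tools) and reciprocal overlap ≥ 0.8 for mono-exonic ones; each
prediction matches at most one truth transcript. Precision, recall and F1
come from the TP/FP/FN counts with zero denominators mapping to 0. TPM
bins use true TPM for recall but reported TPM for precision (a false
prediction has no true TPM); the asymmetry is inherent. Cross-tool
consistency counts, per tool, how many of its chains are supported by
0..k−1 other tools, plus the chains reported by all others but missed by
it.

## Synthetic data generator

The generator emits spliced SAM records directly — no sequence-level
simulation and realignment. Injected coordinate noise stands in for what
an aligner produces from error-prone reads: per-endpoint splice-site
shifts (uniform in ±s with probability `p_shift`), skipping of ≤ 30 bp
exons (`p_skip`), exponential 5′/3′ truncation in transcript coordinates,
a 30 bp soft-clipped polyA tail on reads whose 3′ end is intact, and
mismatches (MD/NM tags) planted near shifted sites, mirroring the
error-near-splice-site signature the correction stage keys on.

Annotation structure: each locus has 5–8 exons; all isoforms share their
first and last junctions and differ internally by dropped exons or
alternative acceptors moved 25–40 bp. Deliberate design constraints, each
forced by an assumption of the method being tested rather than tuned to
any observed score:

* Isoform variants never differ *only* by a ≤ 36 bp exon: the matcher
  defines such a difference as a misalignment artifact, so an isoform pair
  distinguished only by it is unrecoverable by construction.
* New junctions keep both endpoints > 24 bp away from existing ones
  (beyond 2Δ and the collapse window), except the intentional near pair:
  every tenth locus carries two annotated junctions 14 bp apart — inside
  the ONT collapse window, outside the 2Δ confusion zone — derived from a
  junction unique to one isoform so that equal expression keeps the
  support ratio below the 2× removal threshold.
* Genuine short (20–30 bp) exons occur at 3% of internal exons, roughly
  the rarity of microexons in mammalian annotations.
* Reverse-strand loci are emitted with probability 0.5 to exercise
  coordinate mirroring.

The "moderate" noise preset (p_shift 0.15, shift ≤ 6, p_skip 0.3 on short
exons, 30% of reads 5′-truncated with mean 120 bp, 10% 3′-truncated with
mean 60 bp) represents a respectable recent-chemistry ONT dataset.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: base-level error processes and quality strings,
aligner-specific systematic biases (e.g. GT–AG motif snapping), intron
retention and other genuine alternative-splicing noise, expression-
dependent truncation, multi-gene read-through, and genome-scale locus
density. Benchmarks here are desk-scale (50 loci, ~150 isoforms, a few
thousand reads, sizes chosen so the full suite runs in seconds); they
validate the algorithmic contracts, not genome-scale accuracy.

## Known limitations

* Chains differing only in an exon the aligner skips at high rate are
  resolved in favor of the annotated isoform; a hidden isoform of this
  shape is systematically missed (and its skip-chain may surface as a
  false positive).
* Isoforms expressed below `min_fsm_reads` cannot be discovered, only
  assigned/quantified when annotated.
* Ambiguous reads are split uniformly (no EM); abundances of isoforms
  distinguishable only by terminal structure are therefore approximate.
* Annotation-free mode merges loci connected by any overlapping read and
  infers strand by majority, which can mis-orient antisense-dominated
  loci.
* Supplementary (chimeric) alignments are dropped; fusion transcripts are
  out of scope.
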