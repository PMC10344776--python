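"""Assign reads to known isoforms and quantify them.

Runs the reference-based pipeline on a clean synthetic dataset and prints
the assignment-status breakdown and the top transcript counts. Unique
reads count 1.0, ambiguous reads are split 1/k over their candidates, and
inconsistent reads (candidate novel isoforms) are excluded from counting.
"""

from collections import Counter
from pathlib import Path

from longiso import pipeline
from longiso.synth import write_dataset

outdir = Path("scratch/example_quant")
paths, _, genes, expression, _ = write_dataset(
    outdir, seed=11, n_loci=6, isoforms_per_locus=3, total_reads=900,
)

result = pipeline.run_pipeline(
    "reference_based", paths["sam"], paths["gtf"], outdir=outdir / "out"
)

statuses = Counter(a.status for a in result.assignments)
print("assignment statuses:", dict(statuses))
print("\nisoform   simulated  estimated")
for tid, n in sorted(expression.items(), key=lambda kv: -kv[1])[:8]:
    print(f"{tid:10s} {n:9d}  {result.transcript_counts.get(tid, 0.0):9.1f}")
print("\nestimates equal simulated counts on clean data because every")
print("full-length read matches exactly one annotated intron chain.")
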