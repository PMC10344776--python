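"""Repair splice-site shifts in uniquely assigned alignments.

Simulates reads whose every splice site is shifted by up to delta (the
inexact-alignment artifact typical of error-prone long reads), runs the
reference-based pipeline, and measures how many shifted junctions the
correction stage restored to their annotated coordinates.
"""

from pathlib import Path

from longiso import pipeline
from longiso.synth import NoiseModel, write_dataset

outdir = Path("scratch/example_correct")
noise = NoiseModel(p_shift=1.0, shift_max=6)  # ONT delta = 6
paths, _, _, _, truth = write_dataset(
    outdir, seed=3, n_loci=6, isoforms_per_locus=3, total_reads=600,
    noise=noise,
)

result = pipeline.run_pipeline(
    "reference_based", paths["sam"], paths["gtf"], outdir=outdir / "out"
)

n_shifted = n_restored = 0
truth_idx = truth.set_index("read_id")
for rid, read in result.corrected_reads.items():
    shifts = truth_idx.loc[rid, "shifts"]
    if not isinstance(shifts, str) or not shifts:
        continue
    chain = set(read.introns)
    for item in shifts.split(";"):
        orig = tuple(map(int, item.split(">")[0].split(",")))
        n_shifted += 1
        n_restored += orig in chain

print(f"shifted junctions: {n_shifted}; restored exactly: {n_restored} "
      f"({100 * n_restored / n_shifted:.1f}%)")
print(f"corrected alignments written to {outdir/'out'/'corrected_reads.bed'}")
print("\nevery junction within delta of an annotated junction of the")
print("assigned isoform is snapped onto it, so downstream graph building")
print("sees the annotated coordinates instead of the alignment noise.")
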