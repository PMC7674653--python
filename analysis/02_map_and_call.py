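#!/usr/bin/env python
"""Trim, map, deduplicate and call raw variants for both sequencing runs.

Reads the simulated FASTQ from scratch/sim/, writes SAM alignments to
scratch/sim/ and raw VCFs to results/.  The wild-type run is called against
its own reference, so its calls are false positives by construction — they
feed the threshold calibration in the next step.
"""

from pathlib import Path

from clonalvar import align, calling, io, preprocess
from clonalvar.pipeline import PipelineConfig

RESULTS = Path("results")
SCRATCH = Path("scratch/sim")


def main() -> None:
    config = PipelineConfig()
    reference = io.read_fasta(Path("results/sim/reference.fasta"))
    for label in ("wts", "mutant"):
        pairs = io.read_fastq_pairs(SCRATCH / f"{label}_R1.fastq", SCRATCH / f"{label}_R2.fastq")
        trimmed, trim_stats = preprocess.trim_pairs(pairs, config.trim_policy())
        alignments, map_stats = align.map_reads(trimmed, reference)
        n_dup = align.mark_duplicates(alignments)
        profile = align.coverage_profile(alignments, reference.length)
        pileup = calling.build_pileup(align.usable(alignments), reference,
                                      calling.read_sequence_map(trimmed))
        calls = calling.call_variants(pileup, reference, mean_depth=profile.mean_depth)
        io.write_sam(alignments, reference, SCRATCH / f"{label}.sam",
                     read_sequences=calling.read_sequence_map(trimmed))
        io.write_vcf(calls, reference, RESULTS / f"{label}.raw.vcf")
        print(f"{label}: {trim_stats['pairs_out']}/{trim_stats['pairs_in']} pairs after trim, "
              f"{map_stats['mates_mapped']} mates mapped, {n_dup} duplicate pairs, "
              f"mean depth {profile.mean_depth:.1f}x, {len(calls)} raw calls")


if __name__ == "__main__":
    main()
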