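#!/usr/bin/env python
"""Detect copy-number gains and longer losses from comparative coverage.

Rebuilds coverage profiles from the SAM alignments of both runs, calls CNVs
at the default window (100 bp, for the multi-kb duplication) and in
fine-window mode (25 bp, for sub-kilobase losses), and writes BED + TSV
tables shaped like the published CNV/long-change tables.
"""

from pathlib import Path

from clonalvar import align, io, structvar

RESULTS = Path("results")
SCRATCH = Path("scratch/sim")


def main() -> None:
    reference = io.read_fasta(RESULTS / "sim/reference.fasta")
    features = io.read_gff3(RESULTS / "sim/reference.gff3")
    wts_aln, _, _ = io.read_sam(SCRATCH / "wts.sam")
    mut_aln, _, _ = io.read_sam(SCRATCH / "mutant.sam")

    for mode, window, min_windows in (("default", 100, 5),
                                      ("fine", structvar.FINE_WINDOW, structvar.FINE_MIN_WINDOWS)):
        wts_prof = align.coverage_profile(wts_aln, reference.length, window=window)
        mut_prof = align.coverage_profile(mut_aln, reference.length, window=window)
        calls = structvar.detect_cnv(mut_prof, wts_prof, min_windows=min_windows)
        structvar.annotate_cnv_calls(calls, features)
        io.write_bed(calls, reference.id, RESULTS / f"cnv_{mode}.bed")
        io.write_cnv_tsv(calls, RESULTS / f"cnv_{mode}.tsv")
        print(f"{mode} windows ({window} bp): "
              + "; ".join(f"{c.kind} {c.start}-{c.end} ({c.size} bp, ratio {c.copy_ratio:.2f})"
                          for c in calls))
        losses = structvar.losses_as_long_changes(calls, features)
        for lc in losses:
            print(f"  long change {lc.start}-{lc.end} {lc.size} bp: {lc.note}")


if __name__ == "__main__":
    main()
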