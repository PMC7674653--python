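#!/usr/bin/env python
"""Simulate the study's sequencing inputs.

Generates the wild-type reference (100 kb, 30 genes) and one mutant genome
carrying 15 SNPs, 2 short indels, an 8 kb tandem duplication and a 759 bp
deletion, then simulates 150 bp paired reads at 120x (0.5% substitution
error, mean quality Q35) for both the wild-type self-run and the mutant.

Small outputs (reference FASTA/GFF3, truth table) go to results/sim/;
the FASTQ files are large and go to scratch/sim/.
"""

import sys
from pathlib import Path

import numpy as np

from clonalvar import io, synth
from clonalvar.pipeline import PipelineConfig
from clonalvar.study import build_mutation_specs

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RESULTS = Path("results/sim")
SCRATCH = Path("scratch/sim")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(seed=SEED, mean_coverage=120.0)

    genome, features = synth.generate_genome(
        config.genome_length, config.gc_fraction, config.n_genes,
        config.mean_gene_length, seed=config.seed)
    specs = build_mutation_specs(genome, np.random.default_rng(SEED + 1_000))
    mutant, truth = synth.inject_mutations(genome, features, specs)

    io.write_fasta(genome, RESULTS / "reference.fasta")
    io.write_gff3(features, genome, RESULTS / "reference.gff3")
    io.write_truth_tsv(truth, RESULTS / "truth.tsv")

    for label, g, seed in (("wts", genome, SEED + 1), ("mutant", mutant, SEED + 2)):
        pairs = synth.simulate_reads(g, mean_coverage=config.mean_coverage,
                                     error_rate=config.error_rate, seed=seed)
        io.write_fastq_pairs(pairs, SCRATCH / f"{label}_R1.fastq", SCRATCH / f"{label}_R2.fastq")
        print(f"{label}: {len(pairs)} read pairs "
              f"({2 * len(pairs) * config.read_length / g.length:.0f}x)")
    print(f"reference: {genome.length} bp, {len(features)} genes; "
          f"mutant: {mutant.length} bp, {len(truth)} truth variants")
    print(f"wrote {RESULTS} (small) and {SCRATCH} (reads)")


if __name__ == "__main__":
    main()
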