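#!/usr/bin/env python
"""Annotate the passing variants at codon level.

Places each passing call into its gene (or intergenic space), extracts the
affected codon on the coding strand, translates reference and alternate
codons with the bacterial genetic code, and writes a table shaped like the
published per-strain variant list.
"""

from pathlib import Path

from clonalvar import annotate, io

RESULTS = Path("results")


def main() -> None:
    reference = io.read_fasta(RESULTS / "sim/reference.fasta")
    features = io.read_gff3(RESULTS / "sim/reference.gff3")
    calls = [c for c in io.read_vcf(RESULTS / "mutant.filtered.vcf")
             if c.filter_status == "pass"]
    annotated = annotate.annotate_variants(calls, features, reference)
    io.write_annotated_tsv(annotated, RESULTS / "annotated_variants.tsv")
    effects = {}
    for av in annotated:
        effects[av.effect] = effects.get(av.effect, 0) + 1
    print(f"annotated {len(annotated)} passing variants:", effects)
    for av in annotated:
        aa = f" {av.aa_ref}->{av.aa_alt}" if av.aa_ref else ""
        locus = av.locus_tag or "intergenic"
        print(f"  {av.call.position} {av.call.ref_allele}>{av.call.alt_allele} "
              f"{locus} {av.effect}{aa}")


if __name__ == "__main__":
    main()
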