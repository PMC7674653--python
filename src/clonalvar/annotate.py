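"""Codon-level variant effect annotation.

Each passing variant is assigned to the unique gene feature containing it
(or intergenic space) and, for coding SNPs, the affected codon is extracted
on the coding strand and translated with the bacterial/archaeal genetic code
(translation table 11, "*" for stop).  Pseudogenes are annotated as if
coding, with the frame taken from the annotated interval; rRNA/tRNA variants
get no amino acids.  Coding indels are classified frameshift or in-frame by
length arithmetic, amino-acid fields left empty.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .models import AnnotatedVariant, GeneFeature, GenomeRecord, VariantCall, revcomp

TRANSLATION_TABLE = 11

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
EFFECT_STOP_LOST = "stop_lost"
EFFECT_FRAMESHIFT = "frameshift"
EFFECT_INFRAME_INDEL = "inframe_indel"
EFFECT_NON_CODING_GENE = "non_coding_gene"
EFFECT_INTERGENIC = "intergenic"


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=TRANSLATION_TABLE))


def locate_variant(position: int, features: list[GeneFeature]) -> GeneFeature | None:
    """The unique feature containing ``position``, or None for intergenic.

    Features must be non-overlapping; two hits raise an error.
    """
    hits = [f for f in features if f.start <= position <= f.end]
    if len(hits) > 1:
        tags = ", ".join(f.locus_tag for f in hits)
        raise ValueError(f"position {position} is contained in overlapping features: {tags}")
    return hits[0] if hits else None


def codon_context(feature: GeneFeature, position: int) -> tuple[int, int]:
    """(codon_index, offset_in_codon), both 0-based, on the coding strand."""
    if not feature.start <= position <= feature.end:
        raise ValueError(f"position {position} outside feature {feature.locus_tag}")
    if feature.feature_kind not in ("cds", "pseudogene"):
        raise ValueError(f"{feature.locus_tag} is not a coding feature")
    if feature.strand == "+":
        delta = position - feature.start
    else:
        delta = feature.end - position
    return delta // 3, delta % 3


def classify_effect(
    variant: VariantCall,
    feature: GeneFeature | None,
    reference: GenomeRecord,
) -> AnnotatedVariant:
    """Annotate one variant against its containing feature (or intergenic)."""
    seq = reference.sequence
    ref_at = seq[variant.position - 1 : variant.position - 1 + len(variant.ref_allele)]
    if ref_at != variant.ref_allele:
        raise ValueError(
            f"variant ref allele {variant.ref_allele!r} at {variant.position} disagrees "
            f"with reference sequence {ref_at!r}"
        )
    if feature is None:
        return AnnotatedVariant(call=variant, effect=EFFECT_INTERGENIC)

    av = AnnotatedVariant(
        call=variant,
        locus_tag=feature.locus_tag,
        product=feature.product,
        feature_kind=feature.feature_kind,
        strand=feature.strand,
        feature_start=feature.start,
        feature_end=feature.end,
    )
    if feature.feature_kind in ("rrna", "trna"):
        av.effect = EFFECT_NON_CODING_GENE
        return av

    if variant.is_indel:
        shift = abs(len(variant.ref_allele) - len(variant.alt_allele)) % 3
        av.effect = EFFECT_FRAMESHIFT if shift else EFFECT_INFRAME_INDEL
        return av

    # coding SNP: extract the codon on the coding strand and substitute
    codon_index, offset = codon_context(feature, variant.position)
    av.codon_index = codon_index
    if feature.strand == "+":
        codon_start = feature.start + 3 * codon_index  # 1-based
        genomic_codon = seq[codon_start - 1 : codon_start + 2]
        ref_codon = genomic_codon
        alt_base = variant.alt_allele
    else:
        codon_end = feature.end - 3 * codon_index  # 1-based, first coding base
        genomic_codon = seq[codon_end - 3 : codon_end]
        ref_codon = revcomp(genomic_codon)
        alt_base = revcomp(variant.alt_allele)
    if len(ref_codon) < 3:
        # codon truncated by the genome boundary: aa fields stay empty
        av.effect = EFFECT_MISSENSE
        return av
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    av.aa_ref = translate_codon(ref_codon)
    av.aa_alt = translate_codon(alt_codon)
    if av.aa_ref == av.aa_alt:
        av.effect = EFFECT_SYNONYMOUS
    elif av.aa_alt == "*":
        av.effect = EFFECT_NONSENSE
    elif av.aa_ref == "*":
        av.effect = EFFECT_STOP_LOST
    else:
        av.effect = EFFECT_MISSENSE
    return av


def annotate_variants(
    calls: list[VariantCall],
    features: list[GeneFeature],
    reference: GenomeRecord,
) -> list[AnnotatedVariant]:
    return [classify_effect(c, locate_variant(c.position, features), reference) for c in calls]
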