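import numpy as np
import pytest

from clonalvar import annotate, io
from clonalvar.models import GeneFeature, GenomeRecord, VariantCall, revcomp

from .oracles import annotate_by_full_translation

TOY = GenomeRecord("toy", "ATGGAATAA" + "C")  # one CDS "ATG GAA TAA" + padding
TOY_CDS = GeneFeature("G1", "toy protein", 1, 9, "+")


def _published_features():
    """Unique gene features from the packaged published variant table."""
    df = io.load_table3_variants()
    feats = {}
    for row in df.itertuples(index=False):
        if row.locus and row.locus not in feats:
            kind = "pseudogene" if row.feature == "Pseudogene" else (
                "rrna" if "ribosomal RNA" in row.product else "cds")
            feats[row.locus] = GeneFeature(row.locus, row.product, int(row.start),
                                           int(row.end), row.strand, kind)
    return list(feats.values())


class TestLocateVariant:
    def test_positions_fall_in_published_loci(self):
        feats = _published_features()
        assert annotate.locate_variant(863781, feats).locus_tag == "X276_22865"
        assert annotate.locate_variant(1190011, feats) is None  # non-coding row
        assert annotate.locate_variant(5443138, feats).locus_tag == "X276_03000"

    def test_overlapping_features_raise(self):
        feats = [GeneFeature("a", "p", 1, 100, "+"), GeneFeature("b", "p", 50, 150, "+")]
        with pytest.raises(ValueError, match="overlap"):
            annotate.locate_variant(60, feats)


class TestCodonContext:
    @pytest.mark.parametrize(
        "feature,position,expected",
        [
            (GeneFeature("g", "p", 101, 130, "+"), 101, (0, 0)),
            (GeneFeature("g", "p", 101, 130, "+"), 106, (1, 2)),
            (GeneFeature("g", "p", 201, 300, "-"), 300, (0, 0)),
            (GeneFeature("g", "p", 201, 300, "-"), 295, (1, 2)),
        ],
    )
    def test_frame_arithmetic(self, feature, position, expected):
        assert annotate.codon_context(feature, position) == expected

    def test_position_outside_feature_raises(self):
        with pytest.raises(ValueError, match="outside"):
            annotate.codon_context(GeneFeature("g", "p", 101, 130, "+"), 100)


class TestClassifyEffect:
    def test_missense_E_to_K(self):
        av = annotate.classify_effect(VariantCall(4, "G", "A", 50, 45), TOY_CDS, TOY)
        assert (av.aa_ref, av.aa_alt, av.effect) == ("E", "K", "missense")

    def test_synonymous_E_to_E(self):
        av = annotate.classify_effect(VariantCall(6, "A", "G", 50, 45), TOY_CDS, TOY)
        assert (av.aa_ref, av.aa_alt, av.effect) == ("E", "E", "synonymous")

    def test_nonsense_and_stop_lost(self):
        # GAA -> TAA at codon 2
        av = annotate.classify_effect(VariantCall(4, "G", "T", 50, 45), TOY_CDS, TOY)
        assert av.effect == "nonsense" and av.aa_alt == "*"
        # terminal TAA -> CAA
        av2 = annotate.classify_effect(VariantCall(7, "T", "C", 50, 45), TOY_CDS, TOY)
        assert av2.effect == "stop_lost" and av2.aa_ref == "*"

    def test_indels_classified_by_length_arithmetic(self):
        fs = annotate.classify_effect(VariantCall(4, "G", "GT", 50, 45), TOY_CDS, TOY)
        assert fs.effect == "frameshift" and fs.aa_ref == ""
        inframe = annotate.classify_effect(VariantCall(4, "GAAT", "G", 50, 45), TOY_CDS, TOY)
        assert inframe.effect == "inframe_indel"

    def test_non_coding_gene_and_intergenic(self):
        rrna = GeneFeature("r1", "16S ribosomal RNA", 1, 9, "+", "rrna")
        av = annotate.classify_effect(VariantCall(4, "G", "A", 50, 45), rrna, TOY)
        assert av.effect == "non_coding_gene" and av.aa_ref == ""
        inter = annotate.classify_effect(VariantCall(10, "C", "A", 50, 45), None, TOY)
        assert inter.effect == "intergenic" and inter.locus_tag == ""

    def test_ref_allele_mismatch_raises(self):
        with pytest.raises(ValueError, match="disagrees"):
            annotate.classify_effect(VariantCall(4, "C", "A", 50, 45), TOY_CDS, TOY)

    def test_pseudogene_annotated_as_coding(self):
        pseudo = GeneFeature("ps", "collagen-like", 1, 9, "+", "pseudogene")
        av = annotate.classify_effect(VariantCall(4, "G", "A", 50, 45), pseudo, TOY)
        assert (av.aa_ref, av.aa_alt) == ("E", "K")

    def test_random_coding_snps_match_full_translation_oracle(self, toy_genome):
        genome, features = toy_genome
        coding = [f for f in features if f.feature_kind in ("cds", "pseudogene")]
        rng = np.random.default_rng(13)
        n = 0
        while n < 100:
            f = coding[int(rng.integers(len(coding)))]
            p = int(rng.integers(f.start, f.end + 1))
            ref = genome.sequence[p - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            av = annotate.classify_effect(VariantCall(p, ref, alt, 60, 50), f, genome)
            aa_ref, aa_alt, effect = annotate_by_full_translation(genome.sequence, f, p, alt)
            assert (av.aa_ref, av.aa_alt, av.effect) == (aa_ref, aa_alt, effect)
            n += 1

    def test_strand_symmetry(self, toy_genome):
        """Annotating base b->b' on a minus-strand CDS equals annotating the
        reverse-complement position/base on the mirrored plus-strand genome."""
        genome, features = toy_genome
        minus = [f for f in features if f.strand == "-" and f.feature_kind == "cds"]
        rng = np.random.default_rng(29)
        flipped = GenomeRecord("flip", revcomp(genome.sequence))
        L = genome.length
        for f in minus[:2]:
            mirrored = GeneFeature(f.locus_tag, f.product, L - f.end + 1, L - f.start + 1, "+")
            for _ in range(20):
                p = int(rng.integers(f.start, f.end + 1))
                ref = genome.sequence[p - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                av = annotate.classify_effect(VariantCall(p, ref, alt, 60, 50), f, genome)
                p2 = L - p + 1
                av2 = annotate.classify_effect(
                    VariantCall(p2, revcomp(ref), revcomp(alt), 60, 50), mirrored, flipped
                )
                assert (av.aa_ref, av.aa_alt, av.effect) == (av2.aa_ref, av2.aa_alt, av2.effect)
                assert av.codon_index == av2.codon_index

    def test_each_variant_gets_exactly_one_effect(self, toy_genome):
        genome, features = toy_genome
        rng = np.random.default_rng(31)
        calls = []
        for p in rng.choice(np.arange(1, genome.length), size=50, replace=False):
            p = int(p)
            ref = genome.sequence[p - 1]
            calls.append(VariantCall(p, ref, str(rng.choice([b for b in "ACGT" if b != ref])), 60, 50))
        annotated = annotate.annotate_variants(calls, features, genome)
        assert len(annotated) == len(calls)
        known = {"synonymous", "missense", "nonsense", "stop_lost", "frameshift",
                 "inframe_indel", "non_coding_gene", "intergenic"}
        counts = {}
        for av in annotated:
            assert av.effect in known
            counts[av.effect] = counts.get(av.effect, 0) + 1
        assert sum(counts.values()) == len(calls)
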