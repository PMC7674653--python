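"""Synthetic clonal-resequencing data: genomes, mutants, and paired reads.

This module is the desk-scale stand-in for the study design: a wild-type
reference chromosome with annotated genes, mutant genomes that differ from it
by a handful of SNPs, short indels, one multi-kb tandem duplication and one
sub-kb deletion, and Illumina-like 150 bp paired-end reads at 115-221x with
average base quality near Phred 35.  Genomes are emitted linear; the circular
origin is ignored at these scales.
"""

from __future__ import annotations

import itertools

import numpy as np

from .models import GeneFeature, GenomeRecord, ReadPair, TruthVariant, left_align, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i

STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MEAN_COVERAGE = 150.0  # centre of the study's 115-221x range
DEFAULT_READ_LENGTH = 150
DEFAULT_MEAN_QUALITY = 35.0  # reported average Phred of the runs
DEFAULT_QUALITY_SD = 3.0
MIN_PHRED, MAX_PHRED = 2, 41


def encode(seq: str) -> np.ndarray:
    """A/C/G/T string -> uint8 codes 0..3."""
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def _codon_sampler(gc_fraction: float, rng: np.random.Generator):
    """Sampler over the 61 non-stop codons, base-composition weighted."""
    p_base = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    codons, probs = [], []
    for triplet in itertools.product("ACGT", repeat=3):
        codon = "".join(triplet)
        if codon in STOP_CODONS:
            continue
        codons.append(codon)
        probs.append(np.prod([p_base["ACGT".index(b)] for b in codon]))
    probs = np.asarray(probs) / np.sum(probs)
    codon_arr = np.array(codons)

    def sample(n: int) -> str:
        return "".join(codon_arr[rng.choice(len(codon_arr), size=n, p=probs)])

    return sample


def generate_genome(
    length: int,
    gc_fraction: float = 0.30,
    n_genes: int = 30,
    mean_gene_length: int = 900,
    seed: int = 0,
    genome_id: str = "synthetic_chromosome",
) -> tuple[GenomeRecord, list[GeneFeature]]:
    """Generate a random genome with non-overlapping stranded gene features.

    Every CDS starts with ATG, ends with a stop codon, contains no in-frame
    internal stop on its coding strand, and has length a multiple of three.
    Gene lengths vary around ``mean_gene_length``; genes are placed one per
    equal-width slot so they never overlap.  Deterministic for a fixed seed.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if n_genes < 0 or length < 1:
        raise ValueError("length and n_genes must be non-negative")
    if n_genes and length < n_genes * mean_gene_length:
        raise ValueError(
            f"cannot pack {n_genes} genes of mean length {mean_gene_length} into {length} bases"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    seq = list(decode(rng.choice(4, size=length, p=p).astype(np.uint8)))

    features: list[GeneFeature] = []
    if n_genes:
        sample_codons = _codon_sampler(gc_fraction, rng)
        slot = length // n_genes
        kinds = rng.choice(
            ["cds", "pseudogene", "rrna", "trna"], size=n_genes, p=[0.88, 0.05, 0.04, 0.03]
        )
        for i in range(n_genes):
            n_codons = int(np.clip(round(rng.normal(mean_gene_length / 3, mean_gene_length / 15)), 10, None))
            gene_len = 3 * n_codons
            if gene_len + 1 > slot:
                raise ValueError(
                    f"gene of length {gene_len} does not fit in a {slot}-base slot; "
                    "reduce n_genes or mean_gene_length"
                )
            offset = int(rng.integers(0, slot - gene_len))
            start = i * slot + offset + 1  # 1-based
            end = start + gene_len - 1
            cds = "ATG" + sample_codons(n_codons - 2) + ["TAA", "TAG", "TGA"][rng.integers(3)]
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = cds if strand == "+" else revcomp(cds)
            seq[start - 1 : end] = genomic
            features.append(
                GeneFeature(
                    locus_tag=f"SYN_{(i + 1) * 5:05d}",
                    product="hypothetical protein",
                    start=start,
                    end=end,
                    strand=strand,
                    feature_kind=str(kinds[i]),
                )
            )
    return GenomeRecord(id=genome_id, sequence="".join(seq)), features


def inject_mutations(
    genome: GenomeRecord,
    features: list[GeneFeature],
    specs: list[TruthVariant],
) -> tuple[GenomeRecord, list[TruthVariant]]:
    """Apply mutation specs to a genome, returning the mutant and a finalized,
    left-aligned truth table with ref alleles filled from the reference.

    Spec conventions: SNPs give ``alt_allele`` as the new base.  ``insertion``
    gives ``alt_allele`` as the inserted bases (anchor added here).
    ``deletion`` gives ``size`` bases deleted starting after ``position``.
    ``duplication`` inserts a tandem copy of ``[position, position+size-1]``
    immediately after the segment; ``segment_deletion`` removes it.
    """
    seq = genome.sequence
    L = len(seq)

    def span(v: TruthVariant) -> tuple[int, int]:
        if v.kind == "snp":
            return v.position, v.position
        if v.kind == "insertion":
            return v.position, v.position
        if v.kind == "deletion":
            return v.position, v.position + max(v.size, len(v.ref_allele) - 1 if v.ref_allele else 1)
        return v.position, v.position + v.size - 1

    spans = sorted(span(v) for v in specs)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"mutation specs overlap: [{s1},{e1}] and [{s2},{e2}]")
    for v in specs:
        s, e = span(v)
        if not 1 <= s <= e <= L:
            raise ValueError(f"spec at position {v.position} outside genome of length {L}")

    truth: list[TruthVariant] = []
    pieces: list[tuple[int, TruthVariant]] = sorted(
        ((v.position, v) for v in specs), key=lambda t: -t[0]
    )
    mutant = seq
    for _, v in pieces:
        p = v.position
        if v.kind == "snp":
            ref_base = seq[p - 1]
            if v.ref_allele and v.ref_allele != ref_base:
                raise ValueError(
                    f"spec ref allele {v.ref_allele!r} at {p} conflicts with reference base {ref_base!r}"
                )
            if v.alt_allele == ref_base:
                raise ValueError(f"snp alt at {p} equals the reference base")
            mutant = mutant[: p - 1] + v.alt_allele + mutant[p:]
            truth.append(TruthVariant("snp", p, ref_base, v.alt_allele))
        elif v.kind == "insertion":
            anchor = seq[p - 1]
            inserted = v.alt_allele
            if not inserted or set(inserted) - set("ACGT"):
                raise ValueError(f"insertion at {p} needs ACGT alt bases")
            if len(inserted) > 10:
                raise ValueError("short-indel insertions are limited to 10 bases; use duplication")
            mutant = mutant[:p] + inserted + mutant[p:]
            np_, nref, nalt = left_align(p, anchor, anchor + inserted, seq)
            truth.append(TruthVariant("insertion", np_, nref, nalt))
        elif v.kind == "deletion":
            size = v.size or (len(v.ref_allele) - 1)
            if not 1 <= size <= 10:
                raise ValueError("short-indel deletions are limited to 1-10 bases; use segment_deletion")
            anchor = seq[p - 1]
            deleted = seq[p : p + size]
            if v.ref_allele and v.ref_allele != anchor + deleted:
                raise ValueError(f"spec ref allele at {p} conflicts with reference sequence")
            mutant = mutant[:p] + mutant[p + size :]
            np_, nref, nalt = left_align(p, anchor + deleted, anchor, seq)
            truth.append(TruthVariant("deletion", np_, nref, nalt, size=size))
        elif v.kind == "duplication":
            segment = seq[p - 1 : p - 1 + v.size]
            mutant = mutant[: p - 1 + v.size] + segment + mutant[p - 1 + v.size :]
            truth.append(TruthVariant("duplication", p, "", "", size=v.size))
        elif v.kind == "segment_deletion":
            mutant = mutant[: p - 1] + mutant[p - 1 + v.size :]
            truth.append(TruthVariant("segment_deletion", p, "", "", size=v.size))
    truth.sort(key=lambda t: t.position)
    return GenomeRecord(id=genome.id + "_mutant", sequence=mutant), truth


def simulate_reads(
    genome: GenomeRecord,
    mean_coverage: float = DEFAULT_MEAN_COVERAGE,
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: int = 400,
    insert_sd: int = 50,
    error_rate: float = 0.005,
    mean_quality: float = DEFAULT_MEAN_QUALITY,
    quality_sd: float = DEFAULT_QUALITY_SD,
    low_quality_tail_fraction: float = 0.05,
    low_quality_tail_max: int = 15,
    seed: int = 0,
) -> list[ReadPair]:
    """Simulate paired-end reads with independent substitution errors.

    The number of pairs is round(mean_coverage * genome_length /
    (2 * read_length)); fragment starts are uniform over valid positions and
    mate 2 is the reverse complement of the fragment's other end.  Per-base
    Phred scores are drawn from a truncated normal centred at
    ``mean_quality``; a small fraction of mates additionally get a
    low-quality 3' tail so that downstream quality trimming has work to do.
    The quality model is independent of the error process.
    """
    L = genome.length
    if L < insert_mean:
        raise ValueError(f"genome length {L} shorter than insert_mean {insert_mean}")
    if read_length > insert_mean:
        raise ValueError("read_length must not exceed insert_mean")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(mean_coverage * L / (2 * read_length)))
    codes = encode(genome.sequence)

    frag_lens = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int), read_length, L
    )
    starts = rng.integers(1, L - frag_lens + 2)  # 1-based fragment start
    forward = rng.random(n_pairs) < 0.5

    def finish_mate(sub: np.ndarray) -> tuple[str, np.ndarray]:
        """Inject substitution errors and draw qualities for one mate."""
        if error_rate > 0:
            n_err = rng.binomial(len(sub), error_rate)
            if n_err:
                pos = rng.choice(len(sub), size=n_err, replace=False)
                sub = sub.copy()
                sub[pos] = (sub[pos] + rng.integers(1, 4, size=n_err)) % 4
        qual = np.clip(
            np.rint(rng.normal(mean_quality, quality_sd, size=len(sub))), MIN_PHRED, MAX_PHRED
        ).astype(np.int16)
        if low_quality_tail_fraction and rng.random() < low_quality_tail_fraction:
            tail = int(rng.integers(1, low_quality_tail_max + 1))
            qual[-tail:] = MIN_PHRED
        return decode(sub), qual

    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        s0 = int(starts[i]) - 1
        frag = codes[s0 : s0 + int(frag_lens[i])]
        left = frag[:read_length]
        right_rc = 3 - frag[-read_length:][::-1]  # reverse complement in code space
        if forward[i]:
            m1_codes, m2_codes, strand = left, right_rc, "+"
        else:
            m1_codes, m2_codes, strand = right_rc, left, "-"
        m1_seq, m1_qual = finish_mate(m1_codes)
        m2_seq, m2_qual = finish_mate(m2_codes)
        pairs.append(
            ReadPair(
                pair_id=f"sim:{genome.id}:{i:07d}",
                mate1_seq=m1_seq,
                mate2_seq=m2_seq,
                mate1_qual=m1_qual,
                mate2_qual=m2_qual,
                true_origin=int(starts[i]),
                true_strand=strand,
            )
        )
    return pairs
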