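"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere in this package, matching the
convention of bacterial genome annotation tables; conversion to 0-based
half-open happens only at the BED boundary in :mod:`clonalvar.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DNA_ALPHABET = frozenset("ACGT")

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A (linearised) bacterial chromosome or contig."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if set(self.sequence) - DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise ValueError(f"genome {self.id!r} contains non-ACGT characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene annotation with 1-based inclusive coordinates."""

    locus_tag: str
    product: str
    start: int
    end: int
    strand: str  # "+" or "-"
    feature_kind: str = "cds"  # cds | pseudogene | rrna | trna

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.locus_tag}: invalid interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be + or -, got {self.strand!r}")
        if self.feature_kind not in ("cds", "pseudogene", "rrna", "trna"):
            raise ValueError(f"{self.locus_tag}: unknown feature kind {self.feature_kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TruthVariant:
    """Ground-truth record of an injected mutation.

    Encoding follows VCF conventions: short indels carry an anchor base, so an
    insertion of "T" after position p is (p, ref="A", alt="AT") and a deletion
    of "A" after p is (p, ref="CA", alt="C").  ``size`` is only meaningful for
    ``duplication`` and ``segment_deletion`` kinds.
    """

    kind: str  # snp | insertion | deletion | duplication | segment_deletion
    position: int
    ref_allele: str = ""
    alt_allele: str = ""
    size: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "insertion", "deletion", "duplication", "segment_deletion"):
            raise ValueError(f"unknown truth variant kind {self.kind!r}")
        if self.kind == "snp" and self.ref_allele and self.alt_allele:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snp alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("snp ref and alt alleles must differ")
        if self.kind in ("duplication", "segment_deletion") and self.size < 1:
            raise ValueError(f"{self.kind} requires size >= 1")


@dataclass
class ReadPair:
    """A simulated paired-end fragment with its truth record."""

    pair_id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: np.ndarray  # per-base Phred, int
    mate2_qual: np.ndarray
    true_origin: int = 0  # 1-based fragment start on the source genome
    true_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual):
            raise ValueError(f"{self.pair_id}: mate1 sequence/quality length mismatch")
        if len(self.mate2_seq) != len(self.mate2_qual):
            raise ValueError(f"{self.pair_id}: mate2 sequence/quality length mismatch")


@dataclass
class Alignment:
    """A mapped mate.  CIGAR ops are 'M' (match/mismatch), 'I', 'D'."""

    read_id: str
    pair_id: str
    mate: int  # 1 or 2
    ref_start: int  # 1-based inclusive
    cigar: list  # list[(op, length)]
    strand: str
    n_mismatches: int
    query_length: int
    base_quality_sum: float = 0.0
    is_duplicate: bool = False
    is_ambiguous: bool = False

    @property
    def ref_end(self) -> int:
        """1-based inclusive end on the reference."""
        span = sum(n for op, n in self.cigar if op in ("M", "D"))
        return self.ref_start + span - 1

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "I"))


@dataclass
class CoverageProfile:
    """Per-position depth with a windowed summary."""

    window: int
    position_depth: np.ndarray  # length = genome length, per-position depth
    window_depth: np.ndarray  # mean depth per window (last window may be short)

    @property
    def mean_depth(self) -> float:
        return float(self.position_depth.mean()) if len(self.position_depth) else 0.0

    @property
    def genome_length(self) -> int:
        return len(self.position_depth)


@dataclass
class PileupColumn:
    """Per-reference-position tally of aligned bases and gaps.

    ``insertion_events`` / ``deletion_events`` are multisets (dicts of string
    -> count) of inserted / deleted sequences anchored immediately after this
    position.  ``deletion_count`` counts reads whose deletion spans this
    position itself.
    """

    position: int
    base_counts: dict  # base -> count
    deletion_count: int = 0
    insertion_events: dict = field(default_factory=dict)
    deletion_events: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.deletion_count


# filter_status values, in pipeline order
RAW = "raw"
PASS = "pass"
SHARED_WITH_WT = "shared_with_wt"
LOW_RELCOV = "low_relcov"
LOW_FRACTION = "low_fraction"


@dataclass
class VariantCall:
    """A called site; indels are anchored VCF-style (e.g. CA -> C)."""

    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    rel_coverage: float = 0.0
    filter_status: str = RAW

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"pos {self.position}: ref and alt alleles are identical")
        if not 0 < self.alt_count <= self.depth:
            raise ValueError(f"pos {self.position}: alt_count {self.alt_count} vs depth {self.depth}")

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> tuple:
        return (self.position, self.ref_allele, self.alt_allele)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)


@dataclass(frozen=True)
class CalibratedThresholds:
    """Empirical-null filter parameters.

    Defaults are the published wild-type-calibrated values: a variant must be
    covered by more than 25.9% of the strain's average coverage and supported
    by at least 30.8% of the reads at the site.
    """

    rel_cov_min: float = 0.259
    pop_fraction_min: float = 0.308

    def __post_init__(self) -> None:
        if not 0 <= self.rel_cov_min < 1:
            raise ValueError("rel_cov_min must be in [0, 1)")
        if not 0 < self.pop_fraction_min <= 1:
            raise ValueError("pop_fraction_min must be in (0, 1]")


@dataclass
class CnvCall:
    """A copy-number gain or loss interval from comparative coverage."""

    start: int
    end: int
    kind: str  # gain | loss
    copy_ratio: float
    loci: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"CNV end {self.end} < start {self.start}")
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"unknown CNV kind {self.kind!r}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class LongChange:
    """A longer (sub-gene to multi-gene) loss interval, Table-4 shaped."""

    start: int
    end: int
    note: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedVariant:
    """A variant call placed onto the annotation with its coding effect."""

    call: VariantCall
    locus_tag: str = ""
    product: str = ""
    feature_kind: str = "intergenic"
    strand: str = ""
    feature_start: Optional[int] = None
    feature_end: Optional[int] = None
    codon_index: Optional[int] = None
    aa_ref: str = ""
    aa_alt: str = ""
    effect: str = "intergenic"


def left_align(position: int, ref: str, alt: str, sequence: str) -> tuple[int, str, str]:
    """Normalise a variant to its left-most minimal representation.

    Standard VCF normalisation: trim shared trailing bases (extending left
    with the preceding reference base whenever an allele would empty), then
    trim shared leading bases.  ``sequence`` is the full reference;
    ``position`` is 1-based.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if position == 1:
                    raise ValueError("cannot left-extend past the start of the reference")
                position -= 1
                base = sequence[position - 1]
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt
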