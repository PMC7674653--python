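"""Per-site pileups and raw SNV / short-indel calling.

The caller is intentionally permissive (haploid clonal samples, no base
quality weighting): at sufficiently covered sites every non-reference allele
with enough supporting reads yields a raw call, and the downstream
empirical-null filter — not the caller — is what removes noise.  This mirrors
a two-stage design in which tens of raw calls per strain are reduced to a
handful after wild-type-calibrated filtering.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from .models import (
    RAW,
    Alignment,
    GenomeRecord,
    PileupColumn,
    VariantCall,
    left_align,
)
from .synth import encode

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_ALT_COUNT = 3
DEFAULT_MIN_ALT_FRACTION = 0.10


def build_pileup(
    alignments: list[Alignment],
    reference: GenomeRecord,
    read_sequences: dict[str, str],
) -> list[PileupColumn]:
    """Build pileup columns (positions with depth > 0 only).

    ``read_sequences`` maps read_id -> the mate sequence as mapped (reverse
    complemented for minus-strand alignments is NOT expected here: sequences
    must be in read orientation; they are reoriented internally).
    Duplicate/ambiguous alignments must already be excluded by the caller.
    CIGAR deletions increment ``deletion_count`` on each deleted position and
    record a deletion event at their anchor; insertions are recorded at their
    anchor position.
    """
    L = reference.length
    base_counts = np.zeros((L, 4), dtype=np.int32)
    deletion_count = np.zeros(L, dtype=np.int32)
    insertion_events: dict[int, Counter] = defaultdict(Counter)
    deletion_events: dict[int, Counter] = defaultdict(Counter)

    match_pos_chunks: list[np.ndarray] = []
    match_code_chunks: list[np.ndarray] = []

    from .models import revcomp  # local import to avoid cycle noise

    for a in alignments:
        seq = read_sequences[a.read_id]
        if a.strand == "-":
            seq = revcomp(seq)
        codes = encode(seq)
        rpos = a.ref_start - 1  # 0-based ref cursor
        qpos = 0
        for op, n in a.cigar:
            if op == "M":
                if rpos + n > L:
                    raise ValueError(f"alignment {a.read_id}: CIGAR walks past the reference end")
                match_pos_chunks.append(np.arange(rpos, rpos + n, dtype=np.int64))
                match_code_chunks.append(codes[qpos : qpos + n].astype(np.int64))
                rpos += n
                qpos += n
            elif op == "I":
                inserted = seq[qpos : qpos + n]
                insertion_events[rpos][inserted] += 1  # anchored after ref position rpos (1-based)
                qpos += n
            elif op == "D":
                if rpos + n > L:
                    raise ValueError(f"alignment {a.read_id}: CIGAR walks past the reference end")
                deleted = reference.sequence[rpos : rpos + n]
                deletion_events[rpos][deleted] += 1
                deletion_count[rpos : rpos + n] += 1
                rpos += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    if match_pos_chunks:
        pos = np.concatenate(match_pos_chunks)
        code = np.concatenate(match_code_chunks)
        flat = np.bincount(pos * 4 + code, minlength=L * 4)
        base_counts += flat.reshape(L, 4).astype(np.int32)

    columns: list[PileupColumn] = []
    total = base_counts.sum(axis=1) + deletion_count
    for i in np.flatnonzero(total):
        counts = {b: int(base_counts[i, j]) for j, b in enumerate("ACGT") if base_counts[i, j]}
        columns.append(
            PileupColumn(
                position=int(i) + 1,
                base_counts=counts,
                deletion_count=int(deletion_count[i]),
                insertion_events=dict(insertion_events.get(i + 1, {})),
                deletion_events=dict(deletion_events.get(i + 1, {})),
            )
        )
    return columns


def read_sequence_map(pairs) -> dict[str, str]:
    """read_id -> mate sequence (read orientation), for build_pileup."""
    seqs = {}
    for p in pairs:
        seqs[f"{p.pair_id}/1"] = p.mate1_seq
        seqs[f"{p.pair_id}/2"] = p.mate2_seq
    return seqs


def call_variants(
    pileup: list[PileupColumn],
    reference: GenomeRecord,
    mean_depth: float,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_alt_count: int = DEFAULT_MIN_ALT_COUNT,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
) -> list[VariantCall]:
    """Call raw variants from a pileup.

    At each column with depth >= ``min_depth``, every non-reference allele
    (substitution base, insertion, or deletion) with count >= ``min_alt_count``
    and fraction >= ``min_alt_fraction`` qualifies; only the highest-count
    allele is reported per site (ties broken by the lexicographically smallest
    encoded alt allele).  Indels are anchored on the preceding reference base
    and left-aligned.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    seq = reference.sequence
    calls: list[VariantCall] = []
    for col in pileup:
        depth = col.depth
        if depth < min_depth:
            continue
        p = col.position
        ref_base = seq[p - 1]
        candidates: list[tuple[int, str, str, str]] = []  # (count, alt_repr, ref_repr, sort_alt)
        for base, count in col.base_counts.items():
            if base != ref_base:
                candidates.append((count, base, ref_base, base))
        for inserted, count in col.insertion_events.items():
            # anchored at p: REF = base at p, ALT = base + inserted
            candidates.append((count, ref_base + inserted, ref_base, ref_base + inserted))
        for deleted, count in col.deletion_events.items():
            candidates.append((count, ref_base, ref_base + deleted, "-" + deleted))
        qualified = [
            c
            for c in candidates
            if c[0] >= min_alt_count and c[0] / depth >= min_alt_fraction
        ]
        if not qualified:
            continue
        qualified.sort(key=lambda c: (-c[0], c[3]))
        count, alt, ref, _ = qualified[0]
        pos, ref, alt = left_align(p, ref, alt, seq)
        calls.append(
            VariantCall(
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                depth=depth,
                alt_count=count,
                rel_coverage=(depth / mean_depth) if mean_depth > 0 else 0.0,
                filter_status=RAW,
            )
        )
    calls.sort(key=lambda c: (c.position, c.ref_allele, c.alt_allele))
    return calls
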