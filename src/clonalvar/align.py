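"""Read mapping, duplicate marking and coverage.

The mapper is a deliberately simple seed-and-extend aligner for clonal
resequencing against a near-identical reference: exact k-mer seeds vote by
diagonal on both strands, the best diagonals are extended ungapped, and a
banded single-gap alignment (gap sizes up to 10) recovers short indels when
the ungapped mismatch count exceeds a trigger.  Reads whose two best
placements tie are flagged ambiguous and excluded from pileups, mirroring
mapping-quality-zero exclusion.  The reference is treated as linear.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from .models import Alignment, CoverageProfile, GenomeRecord, ReadPair, revcomp
from .synth import encode

DEFAULT_K = 21
DEFAULT_MAX_MISMATCHES = 6
GAP_BAND = 10


class ReferenceIndex:
    """Exact k-mer index of a reference sequence."""

    def __init__(self, reference: GenomeRecord, k: int = DEFAULT_K):
        if k < 11:
            raise ValueError("seed length k must be >= 11")
        if reference.length == 0:
            raise ValueError("empty reference")
        self.reference = reference
        self.k = k
        self.codes = encode(reference.sequence)
        seq = reference.sequence
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(reference.length - k + 1):
            index[seq[i : i + k]].append(i)
        self.index = dict(index)


def _gapped_rescue(read_codes: np.ndarray, ref_codes: np.ndarray, diag: int,
                   band: int = GAP_BAND):
    """Best single-gap banded alignment of a read anchored at ``diag``.

    Tries every gap size 1..band and every split point for one insertion or
    one deletion; cost = mismatches + gap length.  Ties prefer the smaller
    gap, then the leftmost split (canonical, left-aligned placement).
    Returns (cost, gap_size, split, kind) or None.
    """
    l = len(read_codes)
    L = len(ref_codes)
    if diag < 0 or diag + l > L:
        return None
    base_window = ref_codes[diag : diag + l]
    pre = np.concatenate(([0], np.cumsum(read_codes != base_window)))
    best = None
    for s in range(1, band + 1):
        if diag + l + s <= L:
            # deletion of s reference bases after `t` read bases
            ref_b = ref_codes[diag + s : diag + s + l]
            neq = (read_codes != ref_b).astype(np.int64)
            suf = np.concatenate((np.cumsum(neq[::-1])[::-1], [0]))
            costs = pre[1:l] + suf[1:l]
            if len(costs):
                t = int(np.argmin(costs)) + 1
                cand = (int(costs[t - 1]) + s, s, t, "D")
                if best is None or cand < best:
                    best = cand
        if s < l - 1 and diag + l - s <= L:
            # insertion of s read bases after `t` read bases
            ref_c = ref_codes[diag : diag + l - s]
            neq = (read_codes[s:] != ref_c).astype(np.int64)
            suf = np.concatenate((np.cumsum(neq[::-1])[::-1], [0]))
            costs = pre[1 : l - s] + suf[1 : l - s]
            if len(costs):
                t = int(np.argmin(costs)) + 1
                cand = (int(costs[t - 1]) + s, s, t, "I")
                if best is None or cand < best:
                    best = cand
    return best


def _map_one(
    seq: str,
    ref_index: ReferenceIndex,
    max_mismatches: int,
    n_seeds: int = 4,
):
    """Place one mate.  Returns (ref_start, cigar, strand, n_mismatches,
    ambiguous) or None if unmapped."""
    k = ref_index.k
    L = ref_index.reference.length
    l = len(seq)
    if l < k:
        return None
    candidates: Counter = Counter()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        positions = sorted({int(p) for p in np.linspace(0, l - k, n_seeds)})
        for rp in positions:
            for hit in ref_index.index.get(s[rp : rp + k], ()):
                diag = hit - rp
                if 0 <= diag <= L - l:
                    candidates[(strand, diag)] += 1
    if not candidates:
        return None

    scored = []
    for (strand, diag), _votes in candidates.most_common(8):
        s = seq if strand == "+" else revcomp(seq)
        read_codes = encode(s)
        window = ref_index.codes[diag : diag + l]
        m = int(np.count_nonzero(window != read_codes))
        if m <= max_mismatches:
            scored.append((l - m, diag + 1, [("M", l)], strand, m))
            continue
        rescued = _gapped_rescue(read_codes, ref_index.codes, diag)
        if rescued is None:
            continue
        cost, size, t, kind = rescued
        n_mm = cost - size
        if n_mm > max_mismatches:
            continue
        if kind == "D":
            ops = [("M", t), ("D", size), ("M", l - t)]
        else:
            ops = [("M", t), ("I", size), ("M", l - t - size)]
        scored.append((l - cost, diag + 1, ops, strand, n_mm))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[1], t[3]))
    best = scored[0]
    ambiguous = False
    for other in scored[1:]:
        if other[0] == best[0] and (other[1], other[3]) != (best[1], best[3]):
            ambiguous = True
            break
    return best[1], best[2], best[3], best[4], ambiguous


def map_reads(
    pairs: list[ReadPair],
    reference: GenomeRecord,
    k: int = DEFAULT_K,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> tuple[list[Alignment], dict]:
    """Map both mates of every pair.  Unmapped mates are omitted (counted in
    the returned stats); ambiguous placements are flagged, not dropped."""
    ref_index = ReferenceIndex(reference, k=k)
    alignments: list[Alignment] = []
    n_unmapped = n_ambiguous = 0
    for pair in pairs:
        for mate, seq, qual in (
            (1, pair.mate1_seq, pair.mate1_qual),
            (2, pair.mate2_seq, pair.mate2_qual),
        ):
            placed = _map_one(seq, ref_index, max_mismatches)
            if placed is None:
                n_unmapped += 1
                continue
            ref_start, cigar, strand, n_mm, ambiguous = placed
            if ambiguous:
                n_ambiguous += 1
            alignments.append(
                Alignment(
                    read_id=f"{pair.pair_id}/{mate}",
                    pair_id=pair.pair_id,
                    mate=mate,
                    ref_start=ref_start,
                    cigar=cigar,
                    strand=strand,
                    n_mismatches=n_mm,
                    query_length=len(seq),
                    base_quality_sum=float(np.sum(qual)),
                    is_ambiguous=ambiguous,
                )
            )
    stats = {
        "mates_in": 2 * len(pairs),
        "mates_mapped": len(alignments),
        "mates_unmapped": n_unmapped,
        "mates_ambiguous": n_ambiguous,
    }
    return alignments, stats


def mark_duplicates(alignments: list[Alignment]) -> int:
    """Mark duplicate pairs in place; returns the number of duplicate pairs.

    Pairs with both mates mapped that share the same (mate-1 five-prime
    start, mate-2 five-prime start, orientation) signature form a duplicate
    group; the pair with the highest summed base quality is kept.
    """
    by_pair: dict[str, list[Alignment]] = defaultdict(list)
    for a in alignments:
        by_pair[a.pair_id].append(a)
    groups: dict[tuple, list[tuple[float, str, list[Alignment]]]] = defaultdict(list)
    for pair_id, mates in by_pair.items():
        if len(mates) != 2:
            continue
        sig_parts = []
        for a in sorted(mates, key=lambda a: a.mate):
            five_prime = a.ref_start if a.strand == "+" else a.ref_end
            sig_parts.append((five_prime, a.strand))
        signature = tuple(sorted(sig_parts))
        total_quality = sum(a.base_quality_sum for a in mates)
        groups[signature].append((total_quality, pair_id, mates))
    n_dup = 0
    for members in groups.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda t: (-t[0], t[1]))
        for _, _, mates in members[1:]:
            for a in mates:
                a.is_duplicate = True
            n_dup += 1
    return n_dup


def usable(alignments: list[Alignment]) -> list[Alignment]:
    """Alignments that feed pileups: non-duplicate, non-ambiguous."""
    return [a for a in alignments if not a.is_duplicate and not a.is_ambiguous]


def coverage_profile(
    alignments: list[Alignment], reference_length: int, window: int = 100
) -> CoverageProfile:
    """Per-position depth of reference-consuming aligned bases, plus window
    means.  Duplicates and ambiguous alignments are excluded."""
    if window < 1:
        raise ValueError("window must be >= 1")
    diff = np.zeros(reference_length + 1, dtype=np.int64)
    for a in usable(alignments):
        if a.ref_end > reference_length:
            raise ValueError(f"alignment {a.read_id} extends past the reference end")
        diff[a.ref_start - 1] += 1
        diff[a.ref_end] -= 1
    depth = np.cumsum(diff[:-1]).astype(float)
    n_windows = (reference_length + window - 1) // window
    window_depth = np.array(
        [depth[i * window : (i + 1) * window].mean() for i in range(n_windows)]
    )
    return CoverageProfile(window=window, position_depth=depth, window_depth=window_depth)
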