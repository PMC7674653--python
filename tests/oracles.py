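"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written from the operation definitions, not from the
implementation: plain python loops, whole-protein translation, exhaustive
agglomeration.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def sliding_window_crop(qual, window: int, threshold: float) -> int:
    """Brute-force crop length: leading Phred<3 bases removed, then the read
    is kept through the end of the 3'-most window with mean >= threshold."""
    qual = list(qual)
    while qual and qual[0] < 3:
        qual.pop(0)
    n = len(qual)
    if n == 0:
        return 0
    if n < window:
        return n if sum(qual) / n >= threshold else 0
    best = -1
    for s in range(n - window + 1):
        if sum(qual[s : s + window]) / window >= threshold:
            best = s
    return best + window if best >= 0 else 0


def pileup_recount(alignments, read_sequences, reference):
    """Per-position recount of a set of alignments: returns dicts
    position -> {base: n}, position -> deletion_n, anchor -> {ins: n},
    anchor -> {del_seq: n} (all 1-based)."""
    from clonalvar.models import revcomp

    base_counts: dict[int, dict[str, int]] = {}
    del_counts: dict[int, int] = {}
    ins_events: dict[int, dict[str, int]] = {}
    del_events: dict[int, dict[str, int]] = {}
    for a in alignments:
        seq = read_sequences[a.read_id]
        if a.strand == "-":
            seq = revcomp(seq)
        rpos, qpos = a.ref_start, 0  # rpos 1-based
        for op, n in a.cigar:
            if op == "M":
                for i in range(n):
                    d = base_counts.setdefault(rpos + i, {})
                    b = seq[qpos + i]
                    d[b] = d.get(b, 0) + 1
                rpos += n
                qpos += n
            elif op == "I":
                anchor = rpos - 1
                d = ins_events.setdefault(anchor, {})
                s = seq[qpos : qpos + n]
                d[s] = d.get(s, 0) + 1
                qpos += n
            elif op == "D":
                anchor = rpos - 1
                s = reference.sequence[rpos - 1 : rpos - 1 + n]
                d = del_events.setdefault(anchor, {})
                d[s] = d.get(s, 0) + 1
                for i in range(n):
                    del_counts[rpos + i] = del_counts.get(rpos + i, 0) + 1
                rpos += n
    return base_counts, del_counts, ins_events, del_events


def normalize_variant(position: int, ref: str, alt: str, sequence: str):
    """Independent minimal left-aligned representation, derived by comparing
    the mutated haplotype against the reference from scratch."""
    hap = sequence[: position - 1] + alt + sequence[position - 1 + len(ref) :]
    # find the difference window; take the maximal common suffix FIRST so the
    # representation lands at its leftmost placement, then the prefix
    j = 0
    while (
        j < min(len(sequence), len(hap))
        and sequence[len(sequence) - 1 - j] == hap[len(hap) - 1 - j]
    ):
        j += 1
    i = 0
    while i < min(len(sequence), len(hap)) - j and sequence[i] == hap[i]:
        i += 1
    ref_part = sequence[i : len(sequence) - j]
    alt_part = hap[i : len(hap) - j]
    pos = i + 1
    if not ref_part or not alt_part:  # pure indel: anchor on the previous base
        pos -= 1
        ref_part = sequence[pos - 1] + ref_part
        alt_part = sequence[pos - 1] + alt_part
    return pos, ref_part, alt_part


def call_sites(pileup, reference, mean_depth, min_depth, min_alt_count, min_alt_fraction):
    """Exhaustive per-site caller: apply the three rules to every allele of
    every column, keep the best allele per site, normalise independently."""
    out = []
    for col in pileup:
        depth = sum(col.base_counts.values()) + col.deletion_count
        if depth < min_depth:
            continue
        ref_base = reference.sequence[col.position - 1]
        cands = []
        for b, n in col.base_counts.items():
            if b != ref_base:
                cands.append((n, b, ref_base, b))
        for s, n in col.insertion_events.items():
            cands.append((n, ref_base + s, ref_base, ref_base + s))
        for s, n in col.deletion_events.items():
            cands.append((n, ref_base, ref_base + s, "-" + s))
        cands = [c for c in cands if c[0] >= min_alt_count and c[0] / depth >= min_alt_fraction]
        if not cands:
            continue
        cands.sort(key=lambda c: (-c[0], c[3]))
        n, alt, ref, _ = cands[0]
        pos, ref, alt = normalize_variant(col.position, ref, alt, reference.sequence)
        out.append((pos, ref, alt, depth, n))
    return sorted(out)


def annotate_by_full_translation(genome_seq: str, feature, position: int, alt: str):
    """Full-CDS oracle: rebuild the mutant CDS, translate both proteins with
    the bacterial code, and diff them.  Returns (aa_ref, aa_alt, effect)."""
    from clonalvar.models import revcomp

    cds_ref = genome_seq[feature.start - 1 : feature.end]
    mutated = (
        genome_seq[: position - 1] + alt + genome_seq[position:]
    )[feature.start - 1 : feature.end]
    if feature.strand == "-":
        cds_ref, mutated = revcomp(cds_ref), revcomp(mutated)
    prot_ref = str(Seq(cds_ref).translate(table=11))
    prot_alt = str(Seq(mutated).translate(table=11))
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if not diffs:
        idx = (position - feature.start) // 3 if feature.strand == "+" else (feature.end - position) // 3
        return prot_ref[idx], prot_ref[idx], "synonymous"
    (idx,) = diffs
    aa_ref, aa_alt = prot_ref[idx], prot_alt[idx]
    if aa_alt == "*":
        effect = "nonsense"
    elif aa_ref == "*":
        effect = "stop_lost"
    else:
        effect = "missense"
    return aa_ref, aa_alt, effect


def complete_linkage_heights(D: np.ndarray) -> list[float]:
    """Exhaustive complete-linkage agglomeration: recompute every
    inter-cluster maximum pairwise distance at every step."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights
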