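"""Quality trimming and singleton filtering.

Functional stand-in for a Trimmomatic-style stage: leading low-quality bases
are removed, reads are cropped at the 3' end by a sliding-window mean-quality
rule, too-short reads are dropped, and pairs with a dropped mate are removed
entirely (no singletons survive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ReadPair

LEADING_MIN_QUALITY = 3


@dataclass(frozen=True)
class TrimPolicy:
    """Sliding-window trimming parameters (Trimmomatic-like defaults)."""

    window: int = 4
    min_window_quality: float = 15.0
    min_length: int = 36

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_length < 1:
            raise ValueError("window and min_length must be >= 1")


def quality_trim(seq: str, qual: np.ndarray, policy: TrimPolicy):
    """Trim one read; returns (seq, qual) or None if the read is dropped.

    Leading bases below Phred 3 are removed first.  Then, scanning windows of
    ``policy.window`` bases, the read is cropped just after the 3'-most window
    whose mean quality is >= ``policy.min_window_quality`` (a read shorter
    than one window is treated as a single window).  Reads shorter than
    ``policy.min_length`` after cropping are dropped.
    """
    qual = np.asarray(qual)
    lead = 0
    while lead < len(qual) and qual[lead] < LEADING_MIN_QUALITY:
        lead += 1
    seq, qual = seq[lead:], qual[lead:]
    n, w = len(qual), policy.window
    if n == 0:
        return None
    if n < w:
        crop = n if qual.mean() >= policy.min_window_quality else 0
    else:
        means = np.convolve(qual, np.ones(w), mode="valid") / w
        ok = np.flatnonzero(means >= policy.min_window_quality)
        crop = int(ok[-1]) + w if len(ok) else 0
    if crop < policy.min_length:
        return None
    return seq[:crop], qual[:crop]


def trim_pairs(pairs: list[ReadPair], policy: TrimPolicy | None = None) -> tuple[list[ReadPair], dict]:
    """Trim both mates of every pair and drop singletons.

    A pair survives only if both mates survive trimming; the output never
    contains an unpaired mate.  Returns the surviving pairs and summary
    counts.
    """
    policy = policy or TrimPolicy()
    out: list[ReadPair] = []
    n_dropped = 0
    for p in pairs:
        t1 = quality_trim(p.mate1_seq, p.mate1_qual, policy)
        t2 = quality_trim(p.mate2_seq, p.mate2_qual, policy)
        if t1 is None or t2 is None:
            n_dropped += 1
            continue
        out.append(
            ReadPair(
                pair_id=p.pair_id,
                mate1_seq=t1[0],
                mate2_seq=t2[0],
                mate1_qual=t1[1],
                mate2_qual=t2[1],
                true_origin=p.true_origin,
                true_strand=p.true_strand,
            )
        )
    stats = {"pairs_in": len(pairs), "pairs_out": len(out), "pairs_dropped": n_dropped}
    return out, stats
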