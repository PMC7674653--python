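"""Copy-number and longer-change detection from comparative coverage.

A purely depth-comparative detector: each coverage window's copy ratio is the
mutant's normalised depth over the wild type's normalised depth; runs of
consecutive extreme windows become gain/loss calls, with boundaries refined
to base resolution against the per-position depth.  This stands in for
assembly-evidence structural callers — no reassembly or read-pair anomaly
evidence is used.
"""

from __future__ import annotations

import numpy as np

from .models import CnvCall, CoverageProfile, GeneFeature, LongChange

DEFAULT_GAIN_MIN = 1.75
DEFAULT_LOSS_MAX = 0.25
DEFAULT_MIN_WINDOWS = 5

# fine-window mode for sub-kilobase losses
FINE_WINDOW = 25
FINE_MIN_WINDOWS = 4


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last) window indices inclusive."""
    out = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
        else:
            out.append((start, prev))
            start = prev = i
    out.append((start, prev))
    return out


def _merge_runs(
    runs: list[tuple[int, int]],
    max_gap: int = 1,
    bridge_ok=None,
) -> list[tuple[int, int]]:
    """Merge runs separated by small gaps.

    Gaps of one window always merge; wider gaps (up to ``max_gap``) merge
    only when ``bridge_ok(first_gap_window, last_gap_window)`` confirms the
    intervening windows still lean toward the event (hysteresis: a window may
    dip below the calling threshold without splitting a long event, but only
    while it stays beyond the midpoint toward 1).
    """
    merged = []
    for run in runs:
        if merged:
            gap = run[0] - merged[-1][1] - 1
            if gap <= 1 or (
                gap <= max_gap and bridge_ok is not None and bridge_ok(merged[-1][1] + 1, run[0] - 1)
            ):
                merged[-1] = (merged[-1][0], run[1])
                continue
        merged.append(run)
    return merged


def detect_cnv(
    mutant_profile: CoverageProfile,
    wts_profile: CoverageProfile,
    gain_min: float = DEFAULT_GAIN_MIN,
    loss_max: float = DEFAULT_LOSS_MAX,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> list[CnvCall]:
    """Call copy-number gains and losses against a wild-type profile.

    Windows where the wild type has zero depth are masked.  Runs of at least
    ``min_windows`` consecutive windows with ratio >= ``gain_min`` (or <=
    ``loss_max``) are called; same-kind runs separated by <= 1 window merge.
    Boundaries are refined by scanning per-position normalised ratio from the
    run edges inward to the first position crossing the midpoint between the
    threshold and 1; the reported copy ratio is the median window ratio.
    """
    if mutant_profile.window != wts_profile.window:
        raise ValueError("coverage profiles have mismatched window sizes")
    if mutant_profile.genome_length != wts_profile.genome_length:
        raise ValueError("coverage profiles cover different genome lengths")
    m_mean, w_mean = mutant_profile.mean_depth, wts_profile.mean_depth
    if m_mean == 0 or w_mean == 0:
        raise ValueError("cannot compare profiles with zero mean depth")
    m = mutant_profile.window_depth / m_mean
    w = wts_profile.window_depth / w_mean
    valid = w > 0
    ratio = np.full_like(m, np.nan)
    ratio[valid] = m[valid] / w[valid]

    # per-position normalised ratio for boundary refinement, lightly smoothed
    # so single-position sampling dips do not stop the edge scans
    from scipy.ndimage import uniform_filter1d

    wpos = wts_profile.position_depth / w_mean
    mpos = mutant_profile.position_depth / m_mean
    pos_ratio = np.divide(mpos, wpos, out=np.ones_like(mpos), where=wpos > 0)
    pos_ratio = uniform_filter1d(pos_ratio, size=15, mode="nearest")

    window = mutant_profile.window
    n_pos = mutant_profile.genome_length
    calls: list[CnvCall] = []
    for kind, mask, threshold in (
        ("gain", valid & (ratio >= gain_min), gain_min),
        ("loss", valid & (ratio <= loss_max), loss_max),
    ):
        mid = (threshold + 1.0) / 2.0

        def bridge_ok(w0: int, w1: int) -> bool:
            gap = ratio[w0 : w1 + 1]
            if np.isnan(gap).any():
                return False
            return bool((gap >= mid).all() if kind == "gain" else (gap <= mid).all())

        max_gap = max(1, min_windows - 1)
        refined: list[tuple[int, int, int, int]] = []  # (start0, end0, first, last)
        for first, last in _merge_runs(_runs(mask), max_gap=max_gap, bridge_ok=bridge_ok):
            if last - first + 1 < min_windows:
                continue
            raw_start = first * window  # 0-based outer edge
            raw_end = min(last * window + window, n_pos) - 1  # 0-based inclusive
            start, end = raw_start, raw_end

            def crosses(i: int) -> bool:
                r = pos_ratio[i]
                return r >= mid if kind == "gain" else r <= mid

            if crosses(start):
                while start > 0 and crosses(start - 1):
                    start -= 1
            else:
                limit_s = min(raw_start + window, raw_end)
                while start < limit_s and not crosses(start):
                    start += 1
            if crosses(end):
                while end < n_pos - 1 and crosses(end + 1):
                    end += 1
            else:
                limit_e = max(raw_end - window, raw_start)
                while end > limit_e and not crosses(end):
                    end -= 1
            refined.append((start, end, first, last))

        # refinement can pull fragments of one event onto overlapping or
        # nearly-touching intervals; coalesce same-kind calls closer than one
        # window (below the detector's resolution)
        refined.sort()
        for start, end, first, last in refined:
            prev = calls[-1] if calls and calls[-1].kind == kind else None
            if prev is not None and start <= prev.end + window:
                prev.end = max(prev.end, end + 1)
                prev._last = max(prev._last, last)  # type: ignore[attr-defined]
                prev.copy_ratio = float(np.nanmedian(ratio[prev._first : prev._last + 1]))
                continue
            call = CnvCall(
                start=start + 1,
                end=end + 1,
                kind=kind,
                copy_ratio=float(np.nanmedian(ratio[first : last + 1])),
            )
            call._first, call._last = first, last  # type: ignore[attr-defined]
            calls.append(call)
    calls.sort(key=lambda c: c.start)
    return calls


def overlap_loci(start: int, end: int, features: list[GeneFeature]) -> list[str]:
    """Locus tags of features intersecting [start, end] (1-based inclusive),
    in genomic order."""
    hits = [f for f in features if f.start <= end and f.end >= start]
    hits.sort(key=lambda f: f.start)
    return [f.locus_tag for f in hits]


def annotate_cnv_calls(calls: list[CnvCall], features: list[GeneFeature]) -> list[CnvCall]:
    for c in calls:
        c.loci = overlap_loci(c.start, c.end, features)
    return calls


def losses_as_long_changes(calls: list[CnvCall], features: list[GeneFeature]) -> list[LongChange]:
    """Express loss calls as Table-4-shaped records (intergenic or the
    affected locus)."""
    out = []
    for c in calls:
        if c.kind != "loss":
            continue
        loci = overlap_loci(c.start, c.end, features)
        note = "Intergenic" if not loci else "Part of the gene " + ", ".join(loci)
        out.append(LongChange(start=c.start, end=c.end, note=note))
    return out
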