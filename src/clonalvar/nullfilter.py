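"""Empirical-null variant filtering calibrated from wild-type self-calls.

The core idea: resequencing the wild type and calling it against its own
assembly yields only false positives, so the maxima of their relative
coverage and allele fraction bound what sequencing noise can produce.  A
mutant variant is kept only if (a) it was not also called in the wild type,
(b) its site is covered by MORE than ``rel_cov_min`` of the strain's average
coverage (strict, per "more than"), and (c) at least ``pop_fraction_min`` of
the reads at the site support it (inclusive, per "at least").  The published
wild-type-calibrated defaults are 25.9% and 30.8%.
"""

from __future__ import annotations

from .models import (
    LOW_FRACTION,
    LOW_RELCOV,
    PASS,
    SHARED_WITH_WT,
    CalibratedThresholds,
    VariantCall,
)


def calibrate_thresholds(
    wts_self_calls: list[VariantCall],
    fallback: CalibratedThresholds | None = None,
) -> CalibratedThresholds:
    """Thresholds = maxima over the false-positive calls' statistics.

    ``wts_self_calls`` must come from calling the wild-type reads against the
    wild-type reference, so every call is a false positive by construction.
    An empty set returns ``fallback`` unchanged (defaults 0.259 / 0.308).
    """
    fallback = fallback or CalibratedThresholds()
    if not wts_self_calls:
        return fallback
    return CalibratedThresholds(
        rel_cov_min=max(c.rel_coverage for c in wts_self_calls),
        pop_fraction_min=max(c.alt_fraction for c in wts_self_calls),
    )


def subtract_shared(
    mutant_calls: list[VariantCall],
    wts_calls_vs_reference: list[VariantCall],
) -> list[VariantCall]:
    """Mark mutant calls that also appear in the wild type (allele-exact).

    A call is shared iff a wild-type call exists with identical
    (position, ref, alt); matching is exact, not positional.
    Returns the same list, statuses updated in place.
    """
    shared_keys = {c.key for c in wts_calls_vs_reference}
    for call in mutant_calls:
        if call.key in shared_keys:
            call.filter_status = SHARED_WITH_WT
    return mutant_calls


def apply_thresholds(
    calls: list[VariantCall],
    thresholds: CalibratedThresholds,
) -> list[VariantCall]:
    """Assign final filter status to every call not already shared with WT.

    Coverage is compared strictly (> rel_cov_min); the supporting-read
    fraction inclusively (>= pop_fraction_min).  Statuses updated in place.
    """
    for call in calls:
        if call.filter_status == SHARED_WITH_WT:
            continue
        if call.rel_coverage <= thresholds.rel_cov_min:
            call.filter_status = LOW_RELCOV
        elif call.alt_fraction < thresholds.pop_fraction_min:
            call.filter_status = LOW_FRACTION
        else:
            call.filter_status = PASS
    return calls


def passing(calls: list[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.filter_status == PASS]
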